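"""Generate a study-like synthetic cohort and run the full pipeline.

Draws 85 subjects (fixed disposition sizes 22/21/10/32) with
shape-archetype trajectories and shape-tied outcomes, then executes
trajectory classification, disposition categorization, and the whole
inferential battery, printing the headline statistics.
"""

import io

from scctraj import RunConfig, generate_cohort, read_long_csv, run_pipeline
from scctraj.synthetic_cohort import cohort_to_long

cohort = generate_cohort(seed=12)
long_csv = io.StringIO()
cohort_to_long(cohort).to_csv(long_csv, index=False)
long_csv.seek(0)

table = read_long_csv(long_csv)
report = run_pipeline(RunConfig(seed=12), table)
s = report.stats

print(f"subjects: {len(report.per_subject)}   improved: {s['n_improved']}")
print(f"KON cutoff (integrated-group median): {s['kon_cutoff']:.1f}")
print(f"shape counts: {s['shape_counts']}")
print(f"disposition counts: {s['disposition_counts']}")
print(f"k-means validation Cramér's V: {s['kmeans_cramers_v']:.2f}")
vc = s["variance_components"]
print(f"variance components — residual {vc['residual']:.0f}, "
      f"group {vc['var_group']:.0f}, unit {vc['var_unit']:.0f}")
it = s["interaction"]
print(f"moderation: rmse slope {it['params']['rmse']:.1f}, "
      f"interaction {it['params']['rmse:pd_fi']:.1f} "
      f"(negative = fluctuation helps the pooled non-IF group more)")

print()
print("A high Cramér's V says the cutoff-based dispositions coincide with")
print("unsupervised clusters; a residual-dominant variance decomposition")
print("says therapy group and unit membership explain little of the outcome.")
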