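# scctraj

Process-outcome analysis of **self-concept clarity (SCC)** trajectories in
group psychotherapy: does the *shape* of a patient's SCC change during
treatment — steady growth versus transient destabilization — predict the
symptomatic outcome, and does the answer depend on the patient's personality
disposition?

`scctraj` is a Python library (with a thin CLI) for repeated-measures cohorts
in which each patient is measured on the 12-item Self-Concept Clarity Scale
(SCCS, range 12–60) at 4–9 occasions, on the KS-II symptom questionnaire
pre/post therapy, and on the KON-2006 neurotic-personality questionnaire at
baseline.  It is aimed at psychotherapy process-outcome researchers who want
the whole pipeline — trajectory statistics, patient categorization, and the
inferential battery — reproducible from a single long-format CSV.

## What it computes

**Per-subject trajectory statistics.**  Each SCCS series *Y₁…Y_k* gets an
OLS logarithmic trend *Y′ᵢ = a + b·ln(tᵢ)* (tᵢ = occasion index) and a
fluctuation statistic

RMSE = √( Σᵢ (Yᵢ − Y′ᵢ)² / k ),

the population SD of the residuals around the log trend.  Lag-1 differences
dᵢ = Y_{i+1} − Yᵢ are *reliable* when |dᵢ| exceeds the SCCS reliable-change
threshold (RCI = 3.48 raw points), and every series is assigned exactly one
of five shapes: **monotonic increase** (reliable rises only), **"V" shape**
(exactly one reliable drop, immediately followed by a reliable rise),
**discontinuous (other)**, **plateau** (no reliable change), **monotonic
decrease**.

**Personality dispositions.**  Subjects are crossed on
integrated/disintegrated (baseline SCCS ≥ 34, the rounded midpoint of a
clinical and a healthy SCC distribution) and functional/dysfunctional
(baseline KON-2006 below the integrated-group median).  The split is
validated against a k-means clustering of the standardized baseline plane
via Cramér's V.

**Outcome statistics.**  With change = KS-II(pre) − KS-II(post) and
*improvement* = change > 56.6 (the KS-II reliable-change threshold), the
battery runs: likelihood-ratio (G) tests on improvement × shape 2×2 tables
per stratum, Pearson correlations of RMSE with change per disposition
stratum, the moderation regression `change ~ rmse * pd_fi` (pd_fi =
integrated-functional vs the pooled other three) with sequential R², a
two-factor shape × disposition ANOVA with partial η², and an intercept-only
three-level variance-components model (subjects / therapy groups /
therapeutic units) with Wald tests.

**Synthetic cohorts.**  `scctraj.generate_cohort` draws study-like cohorts
(fixed disposition sizes 22/21/10/32, shape-archetype trajectories, outcomes
tied to shape × disposition) with full ground truth, so every stage can be
exercised and power-checked without patient data.

## Worked example

```bash
python examples/03_gtests_from_published_counts.py
```

```
shape                        G         p
V shape                   9.59    0.0020
monotonic increase        3.19    0.0741
monotonic decrease       21.13    0.0000
```

Of 39 improved patients, 20 had a "V"-shaped SCC trajectory against 9 of 46
non-improved patients — G(1) = 9.59, p = 0.002: transient SCC destabilization
with re-integration goes with symptomatic improvement.  No improved patient
showed a monotonic SCC decrease (the zero cell enters as 0·ln 0 = 0), giving
G = 21.13.

The other examples cover shape classification on hand-made series
(`01_shape_classification.py`), the full pipeline on a simulated cohort
(`02_simulate_and_analyze.py`), and the variance-components model
(`04_variance_components.py`).  A small bundled cohort lives at
`examples/data/fixture_cohort.csv`; the CLI runs the same stages from a
shell:

```bash
scctraj analyze examples/data/fixture_cohort.csv --out report/
scctraj simulate --seed 1 --out cohort.csv
scctraj classify cohort.csv
```

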