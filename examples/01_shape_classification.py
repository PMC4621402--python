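"""Classify individual SCC trajectories into the five reliable-change shapes.

Builds a handful of short score series, fits each subject's logarithmic
trend, and prints the fluctuation (RMSE) and shape label.  A difference
between consecutive occasions counts as reliable only when it exceeds
the SCCS reliable-change threshold of 3.48 raw points.
"""

from scctraj import classify_shape, fit_log_trajectory

series = {
    "steady gain": [34, 40, 43, 44, 45],
    "dip and rebound (V)": [38, 39, 33, 41, 42],
    "turbulent": [40, 33, 41, 34, 42],
    "flat": [35, 36, 34, 36, 35],
    "declining": [45, 44, 38, 37, 36],
}

print(f"{'series':<22}{'slope':>8}{'rmse':>8}  shape")
for name, scores in series.items():
    fit = fit_log_trajectory(scores)
    label = classify_shape(scores)
    print(f"{name:<22}{fit.slope:>8.2f}{fit.rmse:>8.2f}  {label.value}")

print()
print("slope: change in SCCS per unit ln(occasion); rmse: SD of the scores")
print("around the fitted log trend (larger = more turbulent trajectory).")
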