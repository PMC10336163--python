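"""Classify a small synthetic cohort end to end.

Simulates two cells per archetype on one trial, runs the full single-cell
pipeline (tuning, ratemap, theta metrics, circular-shift nulls) and prints
the composite labels next to the generator's ground truth, plus the cohort
summary table.
"""

import numpy as np

from thetahd.classification import classify_session_cell
from thetahd.cohort import cohort_summary
from thetahd.synthetic import (ThetaLfpParams, TrajectoryParams, archetype_spec,
                               simulate_cell, simulate_lfp, simulate_trajectory)

tracking = simulate_trajectory(TrajectoryParams(seed=42))
lfp = simulate_lfp(tracking, ThetaLfpParams(seed=43))

rng = np.random.default_rng(5)
reports = []
print(f"{'cell':12s} {'programmed':12s} {'recovered':12s}")
for arch in ("place", "hd", "theta_hd", "theta"):
    for i in range(2):
        spec = archetype_spec(arch, f"{arch}_{i}", rng)
        s = simulate_cell(spec, tracking, lfp, seed=100 + len(reports))
        rep = classify_session_cell(s, tracking, lfp, n_shuffles=200, seed=1)
        reports.append(rep)
        print(f"{spec.cell_id:12s} {arch:12s} {rep.label:12s}")

print("\ncohort summary (mean +/- SEM per recovered class):")
df = cohort_summary(reports)
cols = [c for c in ("n", "mean_rate_mean", "ic_mean", "dir_info_mean",
                    "loc_sparsity_mean") if c in df.columns]
print(df[cols].round(3).to_string())
print("\nLabels follow the conservative criteria: theta requires phase")
print("locking above the cell's own 99th-percentile shuffle threshold plus")
print("autocorrelogram rhythmicity; HD requires a significant R-vector and")
print("a directional peak above 1 Hz; place requires compact, informative")
print("spatial firing, and wins over the other labels when present.")
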