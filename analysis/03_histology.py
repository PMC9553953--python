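"""Motor-neuron densities, per-timepoint group tests and behavior correlations.

Normalizes slice counts to cells per 10^6 px (1024 x 1024 field), averages
slices within each animal (one n per animal), compares WT vs SOD1 with
unpaired pooled-variance t tests at each histology week, and correlates the
SOD1 group-mean densities against the matched behavioral group means
(cortical M1 vs time pulling and time on hindlimbs; spinal L5 ventral horn vs
time on hindlimbs).  Outputs land in results/histology/.

Run from the repository root:  python analysis/03_histology.py
"""

from pathlib import Path

import pandas as pd

from stringpull.histology import density_table
from stringpull.io import load_histology
from stringpull.pipeline import behavior_histology_correlations, histology_tests

root = Path(__file__).resolve().parents[1] / "results"
out = root / "histology"
out.mkdir(parents=True, exist_ok=True)

histology = load_histology(root / "cohort" / "histology.csv")
densities = density_table(histology)
densities.to_csv(out / "densities.csv", index=False)

tests = histology_tests(densities)
tests.to_csv(out / "timepoint_tests.csv", index=False)
print("per-timepoint unpaired t tests (density, cells per 10^6 px):")
for r in tests.itertuples():
    flag = "*" if r.p < 0.05 else " "
    print(f"  week {r.week:>2d} {r.region:<5s} WT {r.wt_mean:7.3f} "
          f"SOD1 {r.sod1_mean:7.3f}  t = {r.t:6.2f}, p = {r.p:.4g} {flag}")

weekly = pd.read_csv(root / "behavior" / "weekly_metrics.csv")
correlations = behavior_histology_correlations(densities, weekly)
correlations.to_csv(out / "correlations.csv", index=False)
print("behavior-histology correlations (SOD1 group means, 4 timepoints):")
for r in correlations.itertuples():
    print(f"  {r.region:<5s} density ~ {r.metric:<20s} R^2 = {r.r_squared:.3f}")
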