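"""Weekly behavioral metrics, z-score onset calls and group comparisons.

Reads the cohort written by 01_simulate_cohort.py, aggregates sessions to
per-animal weekly averages plus relative weight change to week 9, z-scores
the SOD1 weekly group means against the pooled weeks-9-11 SOD1 baseline
(weight against the baseline extrapolated from the WT growth trend), calls
group and per-animal onsets, and runs Sidak-corrected weekly WT-vs-SOD1
comparisons.  Outputs land in results/behavior/.

Run from the repository root:  python analysis/02_behavior_onset.py
"""

from pathlib import Path

import pandas as pd

from stringpull.config import BEHAVIOR_METRICS
from stringpull.io import load_sessions, load_weights
from stringpull.metrics import relative_weight_table, weekly_metrics_table
from stringpull.pipeline import (animal_onsets, behavior_group_onset,
                                 behavior_group_zseries, group_comparisons,
                                 weight_group_onset, weight_group_zseries)

root = Path(__file__).resolve().parents[1] / "results"
out = root / "behavior"
out.mkdir(parents=True, exist_ok=True)

sessions = load_sessions(root / "cohort" / "sessions.csv")
weights = load_weights(root / "cohort" / "weights.csv")
weekly = pd.concat([weekly_metrics_table(sessions),
                    relative_weight_table(weights)], ignore_index=True)
weekly.to_csv(out / "weekly_metrics.csv", index=False)

calls, zrows = [], []
for metric in BEHAVIOR_METRICS:
    z, baseline = behavior_group_zseries(weekly, metric)
    call = behavior_group_onset(weekly, metric)
    calls.append({"level": "group", "metric": metric, "rule": call.rule,
                  "onset_week": call.onset_week})
    zrows += [{"metric": metric, "week": int(w), "z": float(v)} for w, v in z.items()]
    print(f"{metric:<20s} baseline {baseline.mean:6.2f} +/- {baseline.sd:.2f}  "
          f"onset week {call.onset_week}")
zw, _, _ = weight_group_zseries(weekly)
wcall = weight_group_onset(weekly)
calls.append({"level": "group", "metric": "relative_weight",
              "rule": "z_threshold_vs_extrapolated", "onset_week": wcall.onset_week})
zrows += [{"metric": "relative_weight", "week": int(w), "z": float(v)}
          for w, v in zw.items()]
print(f"{'relative_weight':<20s} deviation from extrapolated baseline  "
      f"onset week {wcall.onset_week}")

per_animal = animal_onsets(weekly, weights)
detected = per_animal.dropna(subset=["onset_week"])
print(f"per-animal 20% rule: {len(detected)}/{len(per_animal)} calls detected, "
      f"median week {detected['onset_week'].median():.0f}")

pd.DataFrame(calls).to_csv(out / "onset_calls_group.csv", index=False)
per_animal.to_csv(out / "onset_calls_animal.csv", index=False)
pd.DataFrame(zrows).to_csv(out / "z_series.csv", index=False)

comparisons = group_comparisons(weekly)
comparisons.to_csv(out / "comparisons.csv", index=False)
sig = comparisons[comparisons["significant"]]
print("first Sidak-significant week per metric:",
      {m: int(g['week'].min()) for m, g in sig.groupby('metric')})
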