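"""Generate the default study cohort and write its tidy tables.

Simulates 16 WT and 24 SOD1 littermates tested twice weekly on the
string-pulling task over weeks 9-18, with weekly weights and cross-sectional
motor-neuron histology (n = 6 per group) at weeks 7/11/15/19, and writes
sessions.csv, weights.csv, histology.csv plus a config echo under
results/cohort/.

Run from the repository root:  python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

from stringpull.config import SimConfig
from stringpull.simulate import simulate_cohort

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
out = Path(__file__).resolve().parents[1] / "results" / "cohort"

cfg = SimConfig(seed=seed)
dataset = simulate_cohort(cfg)
dataset.write(out)

print(f"cohort seed {seed} written to {out}")
print(f"  sessions : {len(dataset.sessions):5d} rows "
      f"({dataset.sessions['animal_id'].nunique()} animals x "
      f"{dataset.sessions['week'].nunique()} weeks x {cfg.sessions_per_week} sessions)")
print(f"  weights  : {len(dataset.weights):5d} rows")
print(f"  histology: {len(dataset.histology):5d} slice rows "
      f"({dataset.histology['animal_id'].nunique()} animals)")
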