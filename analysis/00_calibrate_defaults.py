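"""Calibrate the generator defaults that the study reports only indirectly.

Two quantities in the cohort generator are not stated as generative
parameters anywhere and are therefore fixed by brute-force simulation against
the analysis' own summary statistics, then frozen into ``SimConfig``:

1. ``sod1_weight_deficit_slope`` (g/week below the WT growth trend): chosen so
   the expected deviation z of SOD1 relative weight from the extrapolated
   WT-trend baseline is about -0.6 at week 13 — safely past the -0.5 onset
   threshold one week after the programmed week-12 deficit start, while week
   12 itself stays at z = 0.
2. Per-slice MN-count noise SD per region: swept on a grid (500 simulated
   cohorts per grid point) so the mean 4-point group-mean R^2 matches the
   study's printed correlations: 0.91 for M1 density vs time pulling and
   0.83 for L5 ventral-horn density vs time on hindlimbs.

Run from the repository root:  python analysis/00_calibrate_defaults.py
Results are written to results/calibration.json; the frozen values live in
stringpull.config (CAL_* constants).
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from stringpull.config import RegionCoupling, SimConfig
from stringpull.experiments import replicate_correlations
from stringpull.metrics import relative_weight_table
from stringpull.pipeline import weight_group_zseries
from stringpull.metrics import weekly_metrics_table
from stringpull.simulate import simulate_cohort

N_SEEDS_CORR = 500
N_SEEDS_WEIGHT = 300
Z13_TARGET = -0.6
R2_TARGETS = {"M1~time_pulling_s": 0.91, "L5VH~time_hindlimbs_s": 0.83}


def mean_weight_z13(slope: float, seeds) -> float:
    zs = []
    for seed in seeds:
        cfg = dataclasses.replace(SimConfig(), sod1_weight_deficit_slope=slope,
                                  seed=int(seed))
        ds = simulate_cohort(cfg)
        weekly = relative_weight_table(ds.weights)
        z, _, _ = weight_group_zseries(weekly, cfg.baseline_window, cfg.weeks[1])
        zs.append(float(z.loc[13]))
    return float(np.mean(zs))


def calibrate_weight_slope() -> dict:
    seeds = range(10_000, 10_000 + N_SEEDS_WEIGHT)
    probes = [0.15, 0.30]
    z13 = [mean_weight_z13(s, seeds) for s in probes]
    # z13 is linear in the slope (deviation scales with it; baseline SD does not)
    a = (z13[1] - z13[0]) / (probes[1] - probes[0])
    b = z13[0] - a * probes[0]
    slope = (Z13_TARGET - b) / a
    check = mean_weight_z13(round(slope, 2), seeds)
    return {"probes": dict(zip(probes, z13)), "slope": round(slope, 2),
            "mean_z13_at_frozen": check}


def config_with_noise(m1_noise: float, l5_noise: float) -> SimConfig:
    return SimConfig(histology_coupling={
        "M1": RegionCoupling(30.0, "time_pulling_s", 1.0, m1_noise),
        "L5VH": RegionCoupling(12.0, "time_hindlimbs_s", 0.512, l5_noise)})


def calibrate_histology_noise() -> dict:
    seeds = range(20_000, 20_000 + N_SEEDS_CORR)
    grid = [(8.0, 4.5), (9.5, 5.5), (11.0, 6.5), (12.5, 7.5), (14.0, 8.5)]
    sweep = []
    for m1, l5 in grid:
        df = replicate_correlations(config_with_noise(m1, l5), seeds)
        means = df.groupby("pair")["r_squared"].mean().to_dict()
        sweep.append({"m1_noise": m1, "l5_noise": l5, **means})
        print(f"  noise (M1={m1}, L5={l5}) -> mean R^2 {means}")
    sweep_df = pd.DataFrame(sweep)

    # 1 - R^2 grows ~ linearly in noise^2; interpolate each region to target
    chosen = {}
    for region, key, col in (("M1", "M1~time_pulling_s", "m1_noise"),
                             ("L5VH", "L5VH~time_hindlimbs_s", "l5_noise")):
        x = sweep_df[col].to_numpy() ** 2
        y = 1.0 - sweep_df[key].to_numpy()
        coef = np.polyfit(x, y, 1)
        target = 1.0 - R2_TARGETS[key]
        noise = float(np.sqrt((target - coef[1]) / coef[0]))
        chosen[region] = round(noise, 1)

    # local refinement: step each region's noise in 0.1 increments on fresh
    # seeds and keep the value whose mean R^2 is closest to its target
    verify_seeds = range(30_000, 30_000 + N_SEEDS_CORR)
    for region, key in (("M1", "M1~time_pulling_s"),
                        ("L5VH", "L5VH~time_hindlimbs_s")):
        best, best_err = chosen[region], float("inf")
        for delta in (-0.2, -0.1, 0.0, 0.1, 0.2):
            trial = dict(chosen, **{region: round(chosen[region] + delta, 1)})
            df = replicate_correlations(
                config_with_noise(trial["M1"], trial["L5VH"]), verify_seeds)
            err = abs(df.groupby("pair")["r_squared"].mean()[key] - R2_TARGETS[key])
            if err < best_err:
                best, best_err = trial[region], err
        chosen[region] = best
    df = replicate_correlations(config_with_noise(chosen["M1"], chosen["L5VH"]),
                                verify_seeds)
    verified = df.groupby("pair")["r_squared"].mean().to_dict()
    return {"sweep": sweep, "chosen": chosen, "verified_mean_r2": verified}


def main():
    out = {"weight": calibrate_weight_slope()}
    print("weight slope calibration:", out["weight"])
    out["histology"] = calibrate_histology_noise()
    print("frozen histology noise:", out["histology"]["chosen"])
    print("verification mean R^2:", out["histology"]["verified_mean_r2"])
    results = Path(__file__).resolve().parents[1] / "results"
    results.mkdir(exist_ok=True)
    (results / "calibration.json").write_text(json.dumps(out, indent=2) + "\n")
    print("written to results/calibration.json")


if __name__ == "__main__":
    main()
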