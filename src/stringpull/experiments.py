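"""Replicated-cohort recovery experiments.

These drive the simulation-based checks of the analysis: detecting the
programmed group onset week across many simulated cohorts, and measuring the
behavior-histology correlation the calibrated coupling produces.  All
randomness is controlled through explicit per-cohort seeds.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd

from .config import BEHAVIOR_METRICS, SimConfig
from .metrics import relative_weight_table, weekly_metrics_table
from .pipeline import (behavior_group_onset, behavior_histology_correlations,
                       weight_group_onset)
from .histology import density_table
from .simulate import simulate_cohort

CORRELATION_PAIRS = (("M1", "time_pulling_s"), ("L5VH", "time_hindlimbs_s"))


def cohort_seeds(base_seed: int, n: int) -> list:
    """Derive ``n`` independent cohort seeds (< 2**31) from one base seed."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def group_onsets_for_config(config: SimConfig, threshold: float = -0.5) -> dict:
    """Group onset week (or None) per metric for one simulated cohort."""
    ds = simulate_cohort(config)
    weekly = pd.concat([weekly_metrics_table(ds.sessions),
                        relative_weight_table(ds.weights)], ignore_index=True)
    window = config.baseline_window
    out = {}
    for metric in BEHAVIOR_METRICS:
        out[metric] = behavior_group_onset(weekly, metric, window, threshold).onset_week
    out["relative_weight"] = weight_group_onset(
        weekly, window, threshold, end_week=config.weeks[1]).onset_week
    return out


def replicate_group_onsets(base_config: SimConfig, seeds) -> pd.DataFrame:
    """Tidy table of detected group onset weeks per seed and metric."""
    rows = []
    for seed in seeds:
        cfg = dataclasses.replace(base_config, seed=int(seed))
        for metric, week in group_onsets_for_config(cfg).items():
            rows.append({"seed": int(seed), "metric": metric, "onset_week": week})
    return pd.DataFrame(rows)


def modal_week(weeks) -> int | None:
    """Most frequent detected week; earliest on ties; None if nothing detected."""
    observed = [int(w) for w in weeks if w is not None and not pd.isna(w)]
    if not observed:
        return None
    counts = Counter(observed)
    top = max(counts.values())
    return min(w for w, c in counts.items() if c == top)


def correlation_r2_for_config(config: SimConfig,
                              pairs=CORRELATION_PAIRS) -> dict:
    """4-point group-mean R^2 per (region, metric) pair for one cohort."""
    ds = simulate_cohort(config)
    weekly = weekly_metrics_table(ds.sessions)
    dens = density_table(ds.histology)
    corr = behavior_histology_correlations(dens, weekly, pairs=tuple(pairs),
                                           week_map=dict(config.histology_week_map))
    return {f"{r.region}~{r.metric}": r.r_squared for r in corr.itertuples()}


def replicate_correlations(base_config: SimConfig, seeds,
                           pairs=CORRELATION_PAIRS) -> pd.DataFrame:
    rows = []
    for seed in seeds:
        cfg = dataclasses.replace(base_config, seed=int(seed))
        for pair, r2 in correlation_r2_for_config(cfg, pairs).items():
            rows.append({"seed": int(seed), "pair": pair, "r_squared": r2})
    return pd.DataFrame(rows)
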