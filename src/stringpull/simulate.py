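"""Synthetic SOD1*G93A cohort generator.

Generates session-level string-pulling metrics, weekly weights and
cross-sectional motor-neuron slice counts with the statistical structure the
downstream analysis assumes: Gaussian between-animal random intercepts,
Gaussian within-session noise, a piecewise-linear programmed deficit in the
SOD1 group (flat through the baseline window, then a constant decline per
week expressed in SD units), and motor-neuron counts coupled linearly to the
programmed behavioral decline.  Physical quantities are truncated at zero;
time on hindlimbs is additionally capped by time pulling and time pulling by
the 60 s session length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BEHAVIOR_METRICS, GENOTYPES, SimConfig

SESSION_COLUMNS = ["animal_id", "genotype", "sex", "week", "session_index",
                   "time_pulling_s", "time_hindlimbs_s", "length_pulled_cm"]
WEIGHT_COLUMNS = ["animal_id", "genotype", "sex", "week", "weight_g"]
HISTOLOGY_COLUMNS = ["animal_id", "genotype", "week", "region", "slice_id",
                     "mn_count", "field_area_px"]


@dataclass
class CohortDataset:
    """One simulated cohort: sessions, weekly weights, histology slices."""

    sessions: pd.DataFrame
    weights: pd.DataFrame
    histology: pd.DataFrame
    config: SimConfig

    def write(self, outdir) -> None:
        """Write sessions.csv / weights.csv / histology.csv plus a config echo."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.sessions.to_csv(out / "sessions.csv", index=False)
        self.weights.to_csv(out / "weights.csv", index=False)
        self.histology.to_csv(out / "histology.csv", index=False)
        (out / "sim_config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2, sort_keys=True) + "\n")


def _animals(config: SimConfig) -> pd.DataFrame:
    rows = []
    for genotype, n in (("WT", config.n_wt), ("SOD1", config.n_sod1)):
        n_f = int(round(n * config.sex_ratio))
        for i in range(n):
            rows.append({
                "animal_id": f"{genotype}-{i + 1:02d}",
                "genotype": genotype,
                "sex": "F" if i < n_f else "M",
            })
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> CohortDataset:
    """Generate a full cohort; identical config (incl. seed) gives identical data."""
    ss = np.random.SeedSequence(config.seed)
    s_beh, s_wt, s_hist = ss.spawn(3)
    animals = _animals(config)
    sessions = _simulate_sessions(config, animals, np.random.default_rng(s_beh))
    weights = _simulate_weights(config, animals, np.random.default_rng(s_wt))
    histology = _simulate_histology(config, np.random.default_rng(s_hist))
    return CohortDataset(sessions=sessions, weights=weights,
                         histology=histology, config=config)


def _simulate_sessions(config: SimConfig, animals: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    n_animals = len(animals)
    weeks = np.array(list(config.week_range()))
    n_weeks = len(weeks)
    n_sess = config.sessions_per_week
    is_sod1 = (animals["genotype"].to_numpy() == "SOD1")

    values = {}
    for metric in BEHAVIOR_METRICS:
        intercept = rng.normal(0.0, config.animal_sd[metric], size=n_animals)
        noise = rng.normal(0.0, config.noise_sd[metric],
                           size=(n_animals, n_weeks, n_sess))
        deficit = np.array([config.expected_deficit(metric, int(w)) for w in weeks])
        mean = (config.metric_baselines[metric]
                + intercept[:, None, None]
                - np.where(is_sod1[:, None], deficit[None, :], 0.0)[:, :, None])
        values[metric] = mean + noise

    pull = np.clip(values["time_pulling_s"], 0.0, 60.0)
    hind = np.clip(values["time_hindlimbs_s"], 0.0, pull)
    length = np.maximum(values["length_pulled_cm"], 0.0)

    idx_a, idx_w, idx_s = np.meshgrid(
        np.arange(n_animals), np.arange(n_weeks), np.arange(n_sess), indexing="ij")
    df = pd.DataFrame({
        "animal_id": animals["animal_id"].to_numpy()[idx_a.ravel()],
        "genotype": animals["genotype"].to_numpy()[idx_a.ravel()],
        "sex": animals["sex"].to_numpy()[idx_a.ravel()],
        "week": weeks[idx_w.ravel()],
        "session_index": idx_s.ravel() + 1,
        "time_pulling_s": pull.ravel(),
        "time_hindlimbs_s": hind.ravel(),
        "length_pulled_cm": length.ravel(),
    })
    return df[SESSION_COLUMNS]


def _simulate_weights(config: SimConfig, animals: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    n_animals = len(animals)
    weeks = np.array(list(config.week_range()))
    is_sod1 = (animals["genotype"].to_numpy() == "SOD1")
    intercept = rng.normal(0.0, config.weight_animal_sd_g, size=n_animals)
    noise = rng.normal(0.0, config.weight_noise_sd_g, size=(n_animals, len(weeks)))
    growth = config.wt_weight_slope * (weeks - config.weeks[0])
    deficit = config.sod1_weight_deficit_slope * np.maximum(
        0, weeks - config.sod1_weight_deficit_onset_week)
    mean = (config.weight_start_g + intercept[:, None] + growth[None, :]
            - np.where(is_sod1[:, None], deficit[None, :], 0.0))
    w = np.maximum(mean + noise, 0.0)

    idx_a, idx_w = np.meshgrid(np.arange(n_animals), np.arange(len(weeks)),
                               indexing="ij")
    df = pd.DataFrame({
        "animal_id": animals["animal_id"].to_numpy()[idx_a.ravel()],
        "genotype": animals["genotype"].to_numpy()[idx_a.ravel()],
        "sex": animals["sex"].to_numpy()[idx_a.ravel()],
        "week": weeks[idx_w.ravel()],
        "weight_g": w.ravel(),
    })
    return df[WEIGHT_COLUMNS]


def _simulate_histology(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for hweek in config.histology_weeks:
        for region in sorted(config.histology_coupling):
            coupling = config.histology_coupling[region]
            for genotype in GENOTYPES:
                expected = config.expected_mn_count(genotype, region, hweek)
                raw = rng.normal(expected, coupling.noise_sd_count,
                                 size=(config.n_histology_per_group,
                                       config.slices_per_animal))
                counts = np.maximum(np.rint(raw), 0.0).astype(int)
                for a in range(config.n_histology_per_group):
                    animal_id = f"H-{genotype}-w{hweek:02d}-{a + 1:02d}"
                    for s in range(config.slices_per_animal):
                        rows.append({
                            "animal_id": animal_id,
                            "genotype": genotype,
                            "week": hweek,
                            "region": region,
                            "slice_id": f"{animal_id}-{region}-s{s + 1}",
                            "mn_count": counts[a, s],
                            "field_area_px": config.field_area_px,
                        })
    return pd.DataFrame(rows, columns=HISTOLOGY_COLUMNS)


def simulate_histology(config: SimConfig) -> pd.DataFrame:
    """Histology table alone, identical to the one embedded in simulate_cohort."""
    s_hist = np.random.SeedSequence(config.seed).spawn(3)[2]
    return _simulate_histology(config, np.random.default_rng(s_hist))
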