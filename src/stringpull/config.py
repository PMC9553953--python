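"""Study-design configuration for the simulated SOD1*G93A string-pulling cohort.

The defaults encode the study design the analysis assumes: WT and SOD1
littermate groups tested twice weekly on the string-pulling task between
weeks 9 and 18 of age, weekly weight measurements, and cross-sectional
motor-neuron histology at weeks 7, 11, 15 and 19.  The SOD1 group carries a
programmed progressive deficit — flat through the weeks-9-11 baseline
window, then a linear decline expressed in units of the metric's session-level
standard deviation — so that the expected group z score first crosses the
-0.5 onset threshold one week after the deficit begins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

BEHAVIOR_METRICS = ("time_pulling_s", "time_hindlimbs_s", "length_pulled_cm")
RELATIVE_WEIGHT = "relative_weight"
GENOTYPES = ("WT", "SOD1")
SEXES = ("F", "M")
REGIONS = ("M1", "L5VH")

#: region -> behavioral metric whose programmed decline drives MN loss
REGION_BEHAVIOR = {"M1": "time_pulling_s", "L5VH": "time_hindlimbs_s"}

#: histology week -> behavioral week used for coupling and correlation
#: (behavioral testing runs weeks 9-18, so week-7 histology pairs with the
#: first tested week and week-19 histology with the last)
DEFAULT_WEEK_MAP = {7: 9, 11: 11, 15: 15, 19: 18}


class ConfigError(ValueError):
    """Invalid configuration; carries the offending field name."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class RegionCoupling:
    """Linear map from programmed behavioral deficit to expected MN count.

    expected count per field = healthy_count - slope_count_per_unit *
    (programmed deficit of the region's matched behavioral metric at the
    matched behavioral week); Gaussian per-slice noise with SD
    ``noise_sd_count`` is added, then counts are rounded and floored at 0.
    """

    healthy_count: float
    behavior_metric: str
    slope_count_per_unit: float
    noise_sd_count: float

    def __post_init__(self):
        if self.healthy_count <= 0:
            raise ConfigError("healthy_count", "must be > 0")
        if self.behavior_metric not in BEHAVIOR_METRICS:
            raise ConfigError("behavior_metric", f"unknown metric {self.behavior_metric!r}")
        if self.slope_count_per_unit < 0:
            raise ConfigError("slope_count_per_unit", "must be >= 0")
        if self.noise_sd_count < 0:
            raise ConfigError("noise_sd_count", "must be >= 0")


def _default_baselines() -> dict:
    return {"time_pulling_s": 30.0, "time_hindlimbs_s": 20.0, "length_pulled_cm": 80.0}


def _default_noise_sd() -> dict:
    return {"time_pulling_s": 4.0, "time_hindlimbs_s": 3.0, "length_pulled_cm": 12.0}


def _default_animal_sd() -> dict:
    return {"time_pulling_s": 3.0, "time_hindlimbs_s": 2.5, "length_pulled_cm": 10.0}


def _default_coupling() -> dict:
    # Slopes give ~50% MN loss at week 19 (matched behavioral week 18) under
    # the default deficit; noise SDs were frozen from the brute-force
    # calibration sweep in analysis/00_calibrate_defaults.py so that the mean
    # 4-point R^2 over seeds reproduces the study's printed correlations.
    return {
        "M1": RegionCoupling(
            healthy_count=30.0,
            behavior_metric="time_pulling_s",
            slope_count_per_unit=1.0,
            noise_sd_count=CAL_M1_NOISE_SD,
        ),
        "L5VH": RegionCoupling(
            healthy_count=12.0,
            behavior_metric="time_hindlimbs_s",
            slope_count_per_unit=0.512,
            noise_sd_count=CAL_L5VH_NOISE_SD,
        ),
    }


# Frozen outputs of the calibration sweep (analysis/00_calibrate_defaults.py).
CAL_M1_NOISE_SD = 11.0
CAL_L5VH_NOISE_SD = 6.4
CAL_WEIGHT_DEFICIT_SLOPE = 0.22  # g/week decline relative to the WT growth trend


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    All behavioral dispersions are per metric: ``noise_sd`` is the
    within-animal session SD, ``animal_sd`` the between-animal SD of the
    random intercept.  ``deficit_sd`` fixes the SD unit in which the
    programmed SOD1 decline is expressed; when None it defaults to the
    session-level SD sqrt(animal_sd^2 + noise_sd^2).
    """

    n_wt: int = 16
    n_sod1: int = 24
    sex_ratio: float = 0.5
    weeks: tuple = (9, 18)
    sessions_per_week: int = 2
    baseline_window: tuple = (9, 11)
    metric_baselines: Mapping[str, float] = field(default_factory=_default_baselines)
    noise_sd: Mapping[str, float] = field(default_factory=_default_noise_sd)
    animal_sd: Mapping[str, float] = field(default_factory=_default_animal_sd)
    deficit_sd: Mapping[str, float] | None = None
    deficit_onset_week: int = 12
    deficit_slope_sd_per_week: float = 0.5
    weight_start_g: float = 20.0
    wt_weight_slope: float = 0.15
    weight_animal_sd_g: float = 1.5
    weight_noise_sd_g: float = 0.3
    sod1_weight_deficit_onset_week: int = 12
    sod1_weight_deficit_slope: float = CAL_WEIGHT_DEFICIT_SLOPE
    histology_weeks: tuple = (7, 11, 15, 19)
    n_histology_per_group: int = 6
    slices_per_animal: int = 3
    histology_coupling: Mapping[str, RegionCoupling] = field(default_factory=_default_coupling)
    histology_week_map: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_WEEK_MAP))
    field_area_px: int = 1024 * 1024
    seed: int = 0

    def __post_init__(self):
        for name in ("n_wt", "n_sod1", "sessions_per_week", "n_histology_per_group",
                     "slices_per_animal"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(name, "must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio", "must be in [0, 1]")
        if self.weeks[1] < self.weeks[0]:
            raise ConfigError("weeks", "range is empty")
        if self.baseline_window[1] < self.baseline_window[0]:
            raise ConfigError("baseline_window", "range is empty")
        if self.deficit_onset_week < self.baseline_window[1]:
            raise ConfigError("deficit_onset_week",
                              "must lie within or after the baseline window end")
        for mapname in ("metric_baselines", "noise_sd", "animal_sd"):
            m = getattr(self, mapname)
            for metric in BEHAVIOR_METRICS:
                if metric not in m:
                    raise ConfigError(mapname, f"missing metric {metric!r}")
                if m[metric] < 0:
                    raise ConfigError(mapname, f"{metric} must be >= 0")
        if self.deficit_sd is not None:
            for metric, v in self.deficit_sd.items():
                if metric not in BEHAVIOR_METRICS:
                    raise ConfigError("deficit_sd", f"unknown metric {metric!r}")
                if v < 0:
                    raise ConfigError("deficit_sd", f"{metric} must be >= 0")
        for name in ("deficit_slope_sd_per_week", "weight_animal_sd_g",
                     "weight_noise_sd_g", "sod1_weight_deficit_slope"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if self.weight_start_g <= 0:
            raise ConfigError("weight_start_g", "must be > 0")
        if self.field_area_px <= 0:
            raise ConfigError("field_area_px", "must be > 0")
        for region in self.histology_coupling:
            if region not in REGIONS:
                raise ConfigError("histology_coupling", f"unknown region {region!r}")
        for hweek in self.histology_weeks:
            if hweek not in self.histology_week_map:
                raise ConfigError("histology_week_map", f"no behavioral week mapped for {hweek}")

    # -- programmed means ---------------------------------------------------

    def effective_deficit_sd(self, metric: str) -> float:
        """SD unit of the programmed decline for ``metric``."""
        if self.deficit_sd is not None and metric in self.deficit_sd:
            return float(self.deficit_sd[metric])
        return math.hypot(self.animal_sd[metric], self.noise_sd[metric])

    def expected_deficit(self, metric: str, week: int) -> float:
        """Programmed SOD1 deficit (metric units, >= 0) at ``week``."""
        ramp = max(0, week - self.deficit_onset_week)
        return self.deficit_slope_sd_per_week * self.effective_deficit_sd(metric) * ramp

    def expected_metric_mean(self, genotype: str, metric: str, week: int) -> float:
        """Programmed (pre-truncation) mean of ``metric`` at ``week``."""
        base = self.metric_baselines[metric]
        if genotype == "SOD1":
            return base - self.expected_deficit(metric, week)
        return base

    def expected_weight_mean(self, genotype: str, week: int) -> float:
        w = self.weight_start_g + self.wt_weight_slope * (week - self.weeks[0])
        if genotype == "SOD1":
            w -= self.sod1_weight_deficit_slope * max(
                0, week - self.sod1_weight_deficit_onset_week)
        return w

    def expected_mn_count(self, genotype: str, region: str, histology_week: int) -> float:
        """Programmed per-field MN count (pre-rounding/truncation)."""
        c = self.histology_coupling[region]
        if genotype != "SOD1":
            return c.healthy_count
        bweek = self.histology_week_map[histology_week]
        return c.healthy_count - c.slope_count_per_unit * self.expected_deficit(
            c.behavior_metric, bweek)

    def week_range(self):
        return range(self.weeks[0], self.weeks[1] + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["histology_coupling"] = {
            r: asdict(c) for r, c in self.histology_coupling.items()}
        return d
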