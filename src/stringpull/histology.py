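"""Motor-neuron classification, field-density normalization and group statistics.

Spinal motor neurons in the L5 ventral horn are large NeuN+ somata
(cross-sectional area strictly greater than 250 um^2); cortical motor neurons
in layer 5 of M1 are CTIP2+ cells with no size gate.  Counts per imaging
field are normalized to cells per 10^6 pixels of a 1024 x 1024 field,
averaged over slices within an animal (one n per animal), compared between
genotypes per timepoint with an unpaired t test, and correlated against the
matched behavioral group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import REGIONS

SIZE_THRESHOLD_UM2 = 250.0
DEFAULT_FIELD_AREA_PX = 1024 * 1024


@dataclass(frozen=True)
class SomaObject:
    slice_id: str
    region: str
    marker: str           # "NeuN" | "CTIP2"
    size_um2: float

    def __post_init__(self):
        if self.size_um2 <= 0:
            raise ValueError(f"soma size must be > 0, got {self.size_um2}")


@dataclass(frozen=True)
class MNDensity:
    animal_id: str
    genotype: str
    week: int
    region: str
    density: float
    n_slices: int


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    r: float
    r_squared: float
    slope: float
    intercept: float


def classify_motoneurons(objects: Iterable[SomaObject], region: str,
                         size_threshold_um2: float = SIZE_THRESHOLD_UM2) -> int:
    """Count motor neurons among segmented somata of one region.

    L5VH: NeuN+ somata strictly larger than the size threshold.
    M1: CTIP2+ somata, any size.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    objects = list(objects)
    mixed = {o.region for o in objects} - {region}
    if mixed:
        raise ValueError(f"objects from regions {sorted(mixed)} mixed into {region}")
    if region == "L5VH":
        return sum(1 for o in objects
                   if o.marker == "NeuN" and o.size_um2 > size_threshold_um2)
    return sum(1 for o in objects if o.marker == "CTIP2")


def normalize_density(mn_count: float, field_area_px: int = DEFAULT_FIELD_AREA_PX) -> float:
    """Count per field -> cells per 10^6 px: count / field_area_px * 1e6."""
    if field_area_px <= 0:
        raise ValueError(f"field area must be > 0, got {field_area_px}")
    if mn_count < 0:
        raise ValueError(f"count must be >= 0, got {mn_count}")
    return mn_count / field_area_px * 1_000_000


def aggregate_animal(slices: pd.DataFrame) -> MNDensity:
    """Average per-slice densities of one animal/week/region into one n-value."""
    if len(slices) == 0:
        raise ValueError("no slices to aggregate")
    for key in ("animal_id", "week", "region"):
        if slices[key].nunique() > 1:
            raise ValueError(f"slices mix multiple values of {key}: "
                             f"{sorted(slices[key].unique())}")
    dens = [normalize_density(c, a) for c, a in
            zip(slices["mn_count"], slices["field_area_px"])]
    first = slices.iloc[0]
    return MNDensity(animal_id=str(first["animal_id"]), genotype=str(first["genotype"]),
                     week=int(first["week"]), region=str(first["region"]),
                     density=float(np.mean(dens)), n_slices=len(dens))


def density_table(histology: pd.DataFrame) -> pd.DataFrame:
    """Per-animal densities for every (animal, week, region) in a slice table."""
    rows = []
    for _, grp in histology.groupby(["animal_id", "week", "region"], sort=True):
        d = aggregate_animal(grp)
        rows.append({"animal_id": d.animal_id, "genotype": d.genotype,
                     "week": d.week, "region": d.region,
                     "density": d.density, "n_slices": d.n_slices})
    return pd.DataFrame(rows)


def timepoint_test(wt: Sequence[float], sod1: Sequence[float],
                   welch: bool = False):
    """Unpaired two-sided t test of per-animal densities (pooled variance by
    default, Welch optional).  Returns (t, df, p)."""
    a, b = np.asarray(wt, float), np.asarray(sod1, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 animals per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        df = len(a) + len(b) - 2
        return 0.0, float(df), 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    else:
        df = len(a) + len(b) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def correlate_decline(density_means: Sequence[float], behavior_means: Sequence[float],
                      x_name: str = "density", y_name: str = "behavior") -> CorrelationResult:
    """Pearson correlation and OLS fit of behavior on density at matched timepoints."""
    x, y = np.asarray(density_means, float), np.asarray(behavior_means, float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("need >= 3 matched points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    fit = stats.linregress(x, y)
    return CorrelationResult(x_name=x_name, y_name=y_name, n=len(x),
                             r=float(fit.rvalue), r_squared=float(fit.rvalue ** 2),
                             slope=float(fit.slope), intercept=float(fit.intercept))
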