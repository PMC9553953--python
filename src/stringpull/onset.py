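"""Disease-onset detection by deviation from a weeks-9-11 baseline.

Two onset rules are implemented, both applied to weekly series:

* group rule — the SOD1 group's weekly mean is z-scored against the pooled
  per-animal weekly values of the same group inside the baseline window;
  onset is the first post-baseline week with z <= -0.5 (decline metrics).
* animal rule — onset is the first post-baseline week an animal's weekly
  value deviates at least 20% from its own baseline-window mean.

Body weight grows in healthy animals, so a static baseline would mask a
mutant deficit; the group weight rule therefore scores the deviation of the
observed SOD1 relative-weight trajectory from a counterfactual baseline that
follows the WT growth trend, anchored at the SOD1 weeks-9-11 mean.

Weekly WT-vs-SOD1 comparisons use per-week Welch t tests with a Sidak
family-wise correction over the post-baseline weeks tested.  This reproduces
the per-week comparison structure of a mixed-effects multiple-comparisons
analysis without fitting the mixed model; it is an approximation, not an
equivalence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Z_THRESHOLD = -0.5
REL_THRESHOLD = 0.20
BASELINE_WINDOW = (9, 11)


class DegenerateBaselineError(ValueError):
    """Baseline dispersion is zero or undefined; z scores cannot be formed."""


@dataclass(frozen=True)
class Baseline:
    """Mean and sample SD of a series pooled over a reference week window."""

    mean: float
    sd: float
    window: tuple
    scope: str = "group"
    n: int = 0

    @property
    def sd_defined(self) -> bool:
        return self.n >= 2 and math.isfinite(self.sd)


@dataclass(frozen=True)
class OnsetCall:
    level: str            # "group" | "animal"
    metric: str
    rule: str             # "z_threshold" | "relative_20pct"
    onset_week: int | None
    threshold_value: float


def compute_baseline(values: pd.Series, window: tuple = BASELINE_WINDOW,
                     scope: str = "group") -> Baseline:
    """Baseline over a week window from a week-indexed pool of values.

    ``values`` is indexed by week and may carry repeated weeks (one entry per
    animal per week for a group-scope baseline).  The mean is the arithmetic
    mean of the pool; the SD is the sample SD (ddof=1), NaN when the pool has
    a single value.
    """
    s = pd.Series(values, dtype=float)
    pool = s[(s.index >= window[0]) & (s.index <= window[1])]
    if len(pool) == 0:
        raise ValueError(f"no values inside baseline window {window}")
    sd = float(pool.std(ddof=1)) if len(pool) >= 2 else float("nan")
    if len(pool) < 2:
        logger.warning("baseline window %s holds a single value; sd undefined", window)
    return Baseline(mean=float(pool.mean()), sd=sd, window=tuple(window),
                    scope=scope, n=len(pool))


def zscore_series(series: pd.Series, baseline: Baseline,
                  post_baseline_only: bool = True) -> pd.Series:
    """z(w) = (x(w) - baseline.mean) / baseline.sd for weeks after the window."""
    if not baseline.sd_defined or baseline.sd == 0:
        raise DegenerateBaselineError(
            "baseline sd is zero or undefined; z series cannot be computed")
    s = pd.Series(series, dtype=float).sort_index()
    if post_baseline_only:
        s = s[s.index > baseline.window[1]]
    return (s - baseline.mean) / baseline.sd


def _first_crossing(flags: pd.Series, sustain: int) -> int | None:
    """First index whose flag starts a run of ``sustain`` consecutive Trues."""
    idx = list(flags.index)
    vals = flags.to_numpy()
    for i in range(len(vals) - sustain + 1):
        if vals[i:i + sustain].all():
            return int(idx[i])
    return None


def detect_group_onset(z: pd.Series, metric: str = "", threshold: float = Z_THRESHOLD,
                       direction: str = "decline", sustain: int = 1) -> OnsetCall:
    """First week the group z series crosses the threshold (inclusive)."""
    z = pd.Series(z, dtype=float).sort_index()
    if len(z) == 0:
        raise ValueError("empty z series")
    flags = z <= threshold if direction == "decline" else z >= threshold
    week = _first_crossing(flags, sustain)
    return OnsetCall(level="group", metric=metric, rule="z_threshold",
                     onset_week=week, threshold_value=threshold)


def detect_animal_onset(series: pd.Series, animal_baseline: Baseline,
                        metric: str = "", rel_threshold: float = REL_THRESHOLD,
                        sustain: int = 1) -> OnsetCall:
    """First post-baseline week an animal deviates >= 20% below its own baseline."""
    if not (animal_baseline.mean > 0):
        raise ValueError(f"nonpositive baseline mean {animal_baseline.mean}")
    s = pd.Series(series, dtype=float).sort_index()
    s = s[s.index > animal_baseline.window[1]]
    deviation = (s - animal_baseline.mean) / animal_baseline.mean
    week = _first_crossing(deviation <= -rel_threshold, sustain)
    return OnsetCall(level="animal", metric=metric, rule="relative_20pct",
                     onset_week=week, threshold_value=rel_threshold)


def extrapolate_weight_baseline(wt_weekly_means: pd.Series, sod1_baseline: Baseline,
                                end_week: int = 18,
                                anchor_week: float | None = None) -> pd.Series:
    """Counterfactual SOD1 trajectory following the WT growth trend.

    An OLS line is fitted to the WT weekly means up to ``end_week`` and
    re-anchored so it passes through (anchor_week, SOD1 baseline mean); the
    anchor defaults to the midpoint of the baseline window.  Returns the
    projected values on the WT weeks.
    """
    s = pd.Series(wt_weekly_means, dtype=float).sort_index()
    s = s[s.index <= end_week]
    if len(s) < 2:
        raise ValueError("need >= 2 WT weekly means to fit a trend")
    fit = stats.linregress(s.index.to_numpy(float), s.to_numpy())
    if anchor_week is None:
        anchor_week = 0.5 * (sod1_baseline.window[0] + sod1_baseline.window[1])
    weeks = s.index
    return pd.Series(sod1_baseline.mean + fit.slope * (weeks.to_numpy(float) - anchor_week),
                     index=weeks)


def weight_deviation_zseries(sod1_pool: pd.Series, sod1_weekly_mean: pd.Series,
                             wt_weekly_mean: pd.Series,
                             window: tuple = BASELINE_WINDOW,
                             end_week: int = 18):
    """z series of the SOD1 relative-weight deviation from the WT-trend baseline.

    ``sod1_pool`` is the week-indexed pool of per-animal SOD1 relative weights
    (used for the baseline mean and SD); ``sod1_weekly_mean`` and
    ``wt_weekly_mean`` are the per-group weekly mean relative weights.
    Returns (z series over post-baseline weeks, baseline, projected series).
    """
    baseline = compute_baseline(sod1_pool, window=window, scope="group")
    if not baseline.sd_defined or baseline.sd == 0:
        raise DegenerateBaselineError("SOD1 relative-weight baseline sd is degenerate")
    projection = extrapolate_weight_baseline(wt_weekly_mean, baseline, end_week=end_week)
    obs = pd.Series(sod1_weekly_mean, dtype=float).sort_index()
    weeks = obs.index.intersection(projection.index)
    weeks = weeks[weeks > window[1]]
    z = (obs.loc[weeks] - projection.loc[weeks]) / baseline.sd
    return z, baseline, projection


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment p_adj = 1 - (1 - p)^m, capped at 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise ValueError(f"family size {m} must be >= 1")
    # clamp to [p, 1]: mathematically 1-(1-p)^m >= p, but floating point can
    # land a hair below at m = 1
    return min(1.0, max(p, 1.0 - (1.0 - p) ** m))


def weekly_group_comparison(wt: dict, sod1: dict, alpha: float = 0.05,
                            welch: bool = True) -> pd.DataFrame:
    """Per-week two-sided t comparison with Sidak correction.

    ``wt`` and ``sod1`` map week -> array of per-animal weekly values.  Weeks
    with fewer than two animals in either group are skipped (and logged); the
    Sidak family size is the number of weeks actually tested.
    """
    weeks = sorted(set(wt) & set(sod1))
    tested, skipped = [], []
    for w in weeks:
        a, b = np.asarray(wt[w], float), np.asarray(sod1[w], float)
        if len(a) < 2 or len(b) < 2:
            skipped.append(w)
            logger.warning("week %s skipped: fewer than 2 animals per group", w)
            continue
        tested.append((w, a, b))
    m = len(tested)
    rows = []
    for w, a, b in tested:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
        adj = sidak_adjust(float(p), m)
        rows.append({"week": w, "t": float(t), "raw_p": float(p),
                     "adj_p": adj, "significant": adj < alpha})
    return pd.DataFrame(rows, columns=["week", "t", "raw_p", "adj_p", "significant"])
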