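"""End-to-end orchestration: simulate/load -> score -> detect -> test -> correlate.

Every stage is an importable function over tidy tables, so individual stages
produce identical outputs whether run alone or through :func:`run_analysis`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import BEHAVIOR_METRICS, DEFAULT_WEEK_MAP, REGION_BEHAVIOR, SimConfig
from .histology import correlate_decline, density_table, timepoint_test
from .io import load_tables
from .metrics import relative_weight_table, weekly_metrics_table
from .onset import (BASELINE_WINDOW, REL_THRESHOLD, Z_THRESHOLD, OnsetCall,
                    compute_baseline, detect_animal_onset, detect_group_onset,
                    weekly_group_comparison, weight_deviation_zseries,
                    zscore_series)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one input source (directory of CSVs or a
    simulation config), plus the analysis thresholds."""

    input_dir: str | None = None
    sim: SimConfig | None = None
    baseline_window: tuple = BASELINE_WINDOW
    z_threshold: float = Z_THRESHOLD
    rel_threshold: float = REL_THRESHOLD
    alpha: float = 0.05
    welch: bool = True
    sustain: int = 1
    end_week: int = 18
    exclude_animals: tuple = ()

    def __post_init__(self):
        if (self.input_dir is None) == (self.sim is None):
            raise ValueError("exactly one input source required: input_dir or sim")
        import math
        for name in ("z_threshold", "rel_threshold", "alpha"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.sustain < 1:
            raise ValueError("sustain must be >= 1")


@dataclass
class AnalysisReport:
    weekly_metrics: pd.DataFrame
    onset_calls: pd.DataFrame
    comparisons: pd.DataFrame
    densities: pd.DataFrame
    timepoint_tests: pd.DataFrame
    correlations: pd.DataFrame
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage helpers operating on the tidy weekly_metrics table
# ---------------------------------------------------------------------------

def behavior_group_zseries(weekly: pd.DataFrame, metric: str,
                           window: tuple = BASELINE_WINDOW):
    """Group-level z series for one behavioral metric.

    Baseline mean/SD come from the pooled per-animal SOD1 weekly values inside
    the window; x(w) is the SOD1 weekly group mean.
    """
    sod1 = weekly[(weekly["genotype"] == "SOD1") & (weekly["metric"] == metric)]
    pool = sod1.set_index("week")["value"]
    baseline = compute_baseline(pool, window=window, scope="group")
    group_mean = sod1.groupby("week")["value"].mean()
    z = zscore_series(group_mean, baseline)
    return z, baseline


def behavior_group_onset(weekly: pd.DataFrame, metric: str,
                         window: tuple = BASELINE_WINDOW,
                         threshold: float = Z_THRESHOLD,
                         sustain: int = 1) -> OnsetCall:
    z, _ = behavior_group_zseries(weekly, metric, window)
    return detect_group_onset(z, metric=metric, threshold=threshold, sustain=sustain)


def weight_group_zseries(weekly: pd.DataFrame, window: tuple = BASELINE_WINDOW,
                         end_week: int = 18):
    """Deviation z series of SOD1 relative weight from the WT-trend baseline."""
    rel = weekly[weekly["metric"] == "relative_weight"]
    sod1 = rel[rel["genotype"] == "SOD1"]
    wt_means = rel[rel["genotype"] == "WT"].groupby("week")["value"].mean()
    z, baseline, projection = weight_deviation_zseries(
        sod1.set_index("week")["value"], sod1.groupby("week")["value"].mean(),
        wt_means, window=window, end_week=end_week)
    return z, baseline, projection


def weight_group_onset(weekly: pd.DataFrame, window: tuple = BASELINE_WINDOW,
                       threshold: float = Z_THRESHOLD, end_week: int = 18,
                       sustain: int = 1) -> OnsetCall:
    z, _, _ = weight_group_zseries(weekly, window, end_week)
    return detect_group_onset(z, metric="relative_weight", threshold=threshold,
                              sustain=sustain)


def animal_onsets(weekly: pd.DataFrame, weights: pd.DataFrame,
                  window: tuple = BASELINE_WINDOW,
                  rel_threshold: float = REL_THRESHOLD,
                  sustain: int = 1) -> pd.DataFrame:
    """Per-animal 20%-deviation onset calls for SOD1 animals.

    Behavioral metrics use each animal's own weekly averages; weight uses the
    absolute weight in grams against the animal's weeks-9-11 mean (relative
    weight change has a near-zero baseline, making a relative rule ill-posed).
    """
    rows = []
    sod1 = weekly[weekly["genotype"] == "SOD1"]
    for metric in BEHAVIOR_METRICS:
        sub = sod1[sod1["metric"] == metric]
        for animal, grp in sub.groupby("animal_id", sort=True):
            series = grp.set_index("week")["value"]
            baseline = compute_baseline(series, window=window, scope="animal")
            call = detect_animal_onset(series, baseline, metric=metric,
                                       rel_threshold=rel_threshold, sustain=sustain)
            rows.append({"level": "animal", "animal_id": animal, "metric": metric,
                         "rule": call.rule, "onset_week": call.onset_week})
    wsod1 = weights[weights["genotype"] == "SOD1"]
    for animal, grp in wsod1.groupby("animal_id", sort=True):
        series = grp.set_index("week")["weight_g"]
        baseline = compute_baseline(series, window=window, scope="animal")
        call = detect_animal_onset(series, baseline, metric="weight_g",
                                   rel_threshold=rel_threshold, sustain=sustain)
        rows.append({"level": "animal", "animal_id": animal, "metric": "weight_g",
                     "rule": call.rule, "onset_week": call.onset_week})
    return pd.DataFrame(rows)


def group_comparisons(weekly: pd.DataFrame, window: tuple = BASELINE_WINDOW,
                      alpha: float = 0.05, welch: bool = True) -> pd.DataFrame:
    """WT-vs-SOD1 per-week comparisons over post-baseline weeks, per metric."""
    frames = []
    for metric in list(BEHAVIOR_METRICS) + ["relative_weight"]:
        sub = weekly[(weekly["metric"] == metric) & (weekly["week"] > window[1])]
        if sub.empty:
            continue
        grouped = {
            g: {int(w): grp["value"].to_numpy()
                for w, grp in sub[sub["genotype"] == g].groupby("week")}
            for g in ("WT", "SOD1")}
        df = weekly_group_comparison(grouped["WT"], grouped["SOD1"],
                                     alpha=alpha, welch=welch)
        df.insert(0, "metric", metric)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["metric", "week", "t", "raw_p", "adj_p", "significant"])


def histology_tests(densities: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    rows = []
    for (week, region), grp in densities.groupby(["week", "region"], sort=True):
        wt = grp.loc[grp["genotype"] == "WT", "density"].to_numpy()
        sod1 = grp.loc[grp["genotype"] == "SOD1", "density"].to_numpy()
        if len(wt) < 2 or len(sod1) < 2:
            continue
        t, df, p = timepoint_test(wt, sod1, welch=welch)
        rows.append({"week": int(week), "region": region, "t": t, "df": df, "p": p,
                     "wt_mean": wt.mean(), "sod1_mean": sod1.mean()})
    return pd.DataFrame(rows)


def behavior_histology_correlations(densities: pd.DataFrame, weekly: pd.DataFrame,
                                    week_map: dict | None = None,
                                    pairs: tuple = (("M1", "time_pulling_s"),
                                                    ("M1", "time_hindlimbs_s"),
                                                    ("L5VH", "time_hindlimbs_s"))
                                    ) -> pd.DataFrame:
    """Correlate SOD1 group-mean MN density against matched behavioral means.

    Histology weeks outside the behavioral testing range are matched to the
    nearest tested week via ``week_map`` (default 7->9, 11->11, 15->15, 19->18).
    """
    if week_map is None:
        week_map = dict(DEFAULT_WEEK_MAP)
    dens_sod1 = densities[densities["genotype"] == "SOD1"]
    beh_sod1 = weekly[weekly["genotype"] == "SOD1"]
    rows = []
    for region, metric in pairs:
        d = dens_sod1[dens_sod1["region"] == region].groupby("week")["density"].mean()
        b = beh_sod1[beh_sod1["metric"] == metric].groupby("week")["value"].mean()
        hweeks = [hw for hw in d.index if week_map.get(int(hw)) in set(b.index)]
        x = [d.loc[hw] for hw in hweeks]
        y = [b.loc[week_map[int(hw)]] for hw in hweeks]
        res = correlate_decline(x, y, x_name=f"{region}_density", y_name=metric)
        rows.append({"region": region, "metric": metric, "n": res.n, "r": res.r,
                     "r_squared": res.r_squared, "slope": res.slope,
                     "intercept": res.intercept})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# composed run
# ---------------------------------------------------------------------------

def run_analysis(config: RunConfig) -> AnalysisReport:
    from .simulate import simulate_cohort

    if config.sim is not None:
        dataset = simulate_cohort(config.sim)
    else:
        dataset = load_tables(config.input_dir)
    sessions, weights = dataset.sessions, dataset.weights
    if config.exclude_animals:
        excl = set(config.exclude_animals)
        sessions = sessions[~sessions["animal_id"].isin(excl)]
        weights = weights[~weights["animal_id"].isin(excl)]

    weekly = pd.concat([weekly_metrics_table(sessions),
                        relative_weight_table(weights)], ignore_index=True)

    calls = []
    for metric in BEHAVIOR_METRICS:
        c = behavior_group_onset(weekly, metric, config.baseline_window,
                                 config.z_threshold, config.sustain)
        calls.append({"level": "group", "animal_id": "", "metric": metric,
                      "rule": c.rule, "onset_week": c.onset_week})
    wcall = weight_group_onset(weekly, config.baseline_window, config.z_threshold,
                               config.end_week, config.sustain)
    calls.append({"level": "group", "animal_id": "", "metric": "relative_weight",
                  "rule": "z_threshold_vs_extrapolated", "onset_week": wcall.onset_week})
    onset_calls = pd.concat(
        [pd.DataFrame(calls),
         animal_onsets(weekly, weights, config.baseline_window,
                       config.rel_threshold, config.sustain)],
        ignore_index=True)

    comparisons = group_comparisons(weekly, config.baseline_window,
                                    config.alpha, config.welch)
    densities = density_table(dataset.histology)
    tp_tests = histology_tests(densities, welch=False)
    correlations = behavior_histology_correlations(densities, weekly)

    prov = {"package_version": __version__}
    if config.sim is not None:
        cfg_json = json.dumps(config.sim.to_dict(), sort_keys=True)
        prov["seed"] = config.sim.seed
        prov["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    else:
        prov["input_dir"] = str(config.input_dir)
    return AnalysisReport(weekly_metrics=weekly, onset_calls=onset_calls,
                          comparisons=comparisons, densities=densities,
                          timepoint_tests=tp_tests, correlations=correlations,
                          provenance=prov)


def write_report(report: AnalysisReport, outdir) -> Path:
    """Write the CSV bundle and a JSON summary; returns the summary path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.weekly_metrics.to_csv(out / "weekly_metrics.csv", index=False)
    report.onset_calls.to_csv(out / "onset_calls.csv", index=False)
    report.comparisons.to_csv(out / "comparisons.csv", index=False)
    report.densities.to_csv(out / "densities.csv", index=False)
    report.timepoint_tests.to_csv(out / "timepoint_tests.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    group = report.onset_calls[report.onset_calls["level"] == "group"]
    summary = {
        "provenance": report.provenance,
        "group_onsets": {r.metric: (None if pd.isna(r.onset_week) else int(r.onset_week))
                         for r in group.itertuples()},
        "correlations": {f"{r.region}~{r.metric}": round(r.r_squared, 6)
                         for r in report.correlations.itertuples()},
        "n_significant_weeks": {
            m: int(g["significant"].sum())
            for m, g in report.comparisons.groupby("metric")},
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path


def render_report(report: AnalysisReport) -> str:
    """Plain-text summary of onsets, z trajectories, densities and correlations."""
    lines = ["== Group onset calls =="]
    group = report.onset_calls[report.onset_calls["level"] == "group"]
    for r in group.itertuples():
        week = "none" if pd.isna(r.onset_week) else f"week {int(r.onset_week)}"
        lines.append(f"  {r.metric:<20s} {r.rule:<28s} onset: {week}")
    animal = report.onset_calls[report.onset_calls["level"] == "animal"]
    detected = animal["onset_week"].dropna()
    if len(animal):
        if detected.empty:
            lines.append("== Per-animal onsets ==\n  no onsets detected")
        else:
            lines.append("== Per-animal onsets (20% rule) ==")
            for metric, grp in animal.groupby("metric"):
                weeks = grp["onset_week"].dropna().astype(int)
                med = f"median week {weeks.median():.0f}" if len(weeks) else "none detected"
                lines.append(f"  {metric:<20s} {len(weeks)}/{len(grp)} detected, {med}")
    lines.append("== Histology: mean density by week/region (SOD1 vs WT) ==")
    for r in report.timepoint_tests.itertuples():
        lines.append(f"  week {r.week:>2d} {r.region:<5s} WT {r.wt_mean:7.3f}  "
                     f"SOD1 {r.sod1_mean:7.3f}  t={r.t:6.2f} p={r.p:.4g}")
    lines.append("== Behavior-histology correlations (group means) ==")
    for r in report.correlations.itertuples():
        lines.append(f"  {r.region:<5s} density ~ {r.metric:<20s} "
                     f"R^2 = {r.r_squared:.3f} (n = {r.n})")
    return "\n".join(lines)


def plot_report(report: AnalysisReport, outdir) -> list:
    """Optional matplotlib panels (weekly group means, densities); returns paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    fig, axes = plt.subplots(1, 4, figsize=(16, 3.5))
    for ax, metric in zip(axes, list(BEHAVIOR_METRICS) + ["relative_weight"]):
        sub = report.weekly_metrics[report.weekly_metrics["metric"] == metric]
        for genotype, grp in sub.groupby("genotype"):
            m = grp.groupby("week")["value"].mean()
            sem = grp.groupby("week")["value"].sem()
            ax.errorbar(m.index, m, yerr=sem, label=genotype, marker="o", ms=3)
        ax.set_title(metric)
        ax.set_xlabel("week")
        ax.legend(fontsize=7)
    fig.tight_layout()
    p = out / "weekly_means.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
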