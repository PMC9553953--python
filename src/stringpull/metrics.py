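"""Session scoring and weekly aggregation for the string-pulling task.

A 60 s recording is annotated as pull events, each an interval on the session
clock with a posture (standing on hindlimbs vs seated) and the string
displacement it produced.  The three session metrics are:

* time_pulling_s   — occupancy of the union of all pull intervals,
* time_hindlimbs_s — occupancy of the union of standing-posture intervals,
* length_pulled_cm — total string displacement summed over events.

Time metrics merge overlapping annotations (time is occupancy); displacement
is cumulative, so it sums.  Seated pulling therefore counts toward time
pulling but not toward time on hindlimbs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

SESSION_LENGTH_S = 60.0
POSTURES = ("standing", "seated")


class EventValidationError(ValueError):
    """A pull event violates the session-clock or displacement constraints."""


@dataclass(frozen=True)
class PullEvent:
    start_s: float
    end_s: float
    posture: str
    displacement_cm: float


def _validate_event(event: PullEvent, index: int) -> None:
    if not (0.0 <= event.start_s < event.end_s <= SESSION_LENGTH_S):
        raise EventValidationError(
            f"event {index}: interval ({event.start_s}, {event.end_s}) must satisfy "
            f"0 <= start < end <= {SESSION_LENGTH_S:g}")
    if event.posture not in POSTURES:
        raise EventValidationError(
            f"event {index}: posture {event.posture!r} not in {POSTURES}")
    if event.displacement_cm < 0:
        raise EventValidationError(
            f"event {index}: displacement {event.displacement_cm} must be >= 0")


def _union_length(intervals: Sequence[tuple]) -> float:
    """Total length of the union of closed intervals."""
    total = 0.0
    end = -1.0
    for start, stop in sorted(intervals):
        if start > end:
            total += stop - start
            end = stop
        elif stop > end:
            total += stop - end
            end = stop
    return total


def score_session(events: Iterable[PullEvent]) -> dict:
    """Compute the three session metrics from annotated pull events.

    Returns a dict with keys time_pulling_s, time_hindlimbs_s and
    length_pulled_cm.  Raises :class:`EventValidationError` identifying the
    first offending event.
    """
    events = list(events)
    for i, ev in enumerate(events):
        _validate_event(ev, i)
    return {
        "time_pulling_s": _union_length([(e.start_s, e.end_s) for e in events]),
        "time_hindlimbs_s": _union_length(
            [(e.start_s, e.end_s) for e in events if e.posture == "standing"]),
        "length_pulled_cm": float(sum(e.displacement_cm for e in events)),
    }


def weekly_average(sessions: pd.DataFrame, metric: str) -> pd.Series:
    """Per-week arithmetic mean of one animal's session metrics.

    ``sessions`` must hold a single animal's rows with ``week`` and the metric
    column; weeks with no sessions are simply absent from the result.
    """
    if "animal_id" in sessions.columns and sessions["animal_id"].nunique() > 1:
        raise ValueError("weekly_average expects sessions of a single animal")
    out = sessions.groupby("week")[metric].mean()
    out.index = out.index.astype(int)
    return out.sort_index()


def relative_weight(weights: Mapping[int, float] | pd.Series,
                    reference_week: int = 9) -> pd.Series:
    """Relative weight change to the reference week, as a signed fraction."""
    s = pd.Series(weights, dtype=float).sort_index()
    if reference_week not in s.index:
        raise ValueError(f"reference week {reference_week} missing from weights")
    ref = s.loc[reference_week]
    if ref <= 0:
        raise ValueError(f"nonpositive reference weight {ref} at week {reference_week}")
    return (s - ref) / ref


def weekly_metrics_table(sessions: pd.DataFrame,
                         metrics: Sequence[str] = ("time_pulling_s",
                                                   "time_hindlimbs_s",
                                                   "length_pulled_cm")) -> pd.DataFrame:
    """Tidy per-animal weekly averages: animal_id, genotype, sex, metric, week, value."""
    keys = ["animal_id", "genotype", "sex", "week"]
    wide = sessions.groupby(keys, as_index=False)[list(metrics)].mean()
    tidy = wide.melt(id_vars=keys, value_vars=list(metrics),
                     var_name="metric", value_name="value")
    return tidy.sort_values(["metric", "animal_id", "week"]).reset_index(drop=True)


def relative_weight_table(weights: pd.DataFrame, reference_week: int = 9) -> pd.DataFrame:
    """Tidy relative weight change per animal (metric = 'relative_weight')."""
    rows = []
    for (animal, genotype, sex), grp in weights.groupby(
            ["animal_id", "genotype", "sex"], sort=True):
        series = relative_weight(
            grp.set_index("week")["weight_g"], reference_week=reference_week)
        for week, value in series.items():
            rows.append({"animal_id": animal, "genotype": genotype, "sex": sex,
                         "metric": "relative_weight", "week": int(week),
                         "value": float(value)})
    return pd.DataFrame(rows)
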