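import numpy as np
import pytest

from stringpull.config import SimConfig
from stringpull.metrics import PullEvent


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort, shared across read-only tests."""
    from stringpull.simulate import simulate_cohort
    return simulate_cohort(SimConfig(seed=1))


def union_oracle_ms(intervals):
    """Interval-union length by 1 ms discretization of the 60 s session.

    Exact for intervals whose endpoints lie on the millisecond grid.
    """
    grid = np.zeros(60_000, dtype=bool)
    for start, end in intervals:
        grid[int(round(start * 1000)):int(round(end * 1000))] = True
    return grid.sum() / 1000.0


def random_event_set(rng, max_events=8):
    """Random valid pull events with millisecond-resolution endpoints."""
    events = []
    for _ in range(rng.integers(0, max_events + 1)):
        a, b = sorted(rng.integers(0, 60_001, size=2))
        if a == b:
            continue
        events.append(PullEvent(
            start_s=a / 1000.0, end_s=b / 1000.0,
            posture=("standing", "seated")[rng.integers(0, 2)],
            displacement_cm=float(rng.uniform(0, 30))))
    return events
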