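"""Baseline z-score machinery, onset rules, extrapolation and Sidak correction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stringpull.onset import (Baseline, DegenerateBaselineError, compute_baseline,
                              detect_animal_onset, detect_group_onset,
                              extrapolate_weight_baseline, sidak_adjust,
                              weekly_group_comparison, zscore_series)


def series(d):
    return pd.Series(d, dtype=float)


class TestBaseline:
    def test_constant_pool(self):
        b = compute_baseline(series({9: 10.0, 10: 10.0, 11: 10.0}))
        assert (b.mean, b.sd) == (10.0, 0.0)

    def test_sample_sd(self):
        b = compute_baseline(series({9: 8.0, 10: 10.0, 11: 12.0}))
        assert b.mean == 10.0
        assert b.sd == pytest.approx(2.0)

    def test_pooled_repeated_weeks(self):
        pool = pd.Series([8.0, 12.0, 10.0, 10.0], index=[9, 9, 10, 11])
        b = compute_baseline(pool)
        assert b.mean == 10.0
        assert b.n == 4

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="no values"):
            compute_baseline(series({14: 3.0}), window=(9, 11))

    def test_single_value_flags_undefined_sd(self):
        b = compute_baseline(series({9: 5.0}))
        assert math.isnan(b.sd) and not b.sd_defined


class TestZScore:
    def test_identity_zero_and_threshold_value(self):
        b = Baseline(mean=10.0, sd=2.0, window=(9, 11), n=3)
        z = zscore_series(series({12: 10.0, 13: 9.0}), b)
        assert z.loc[12] == 0.0
        assert z.loc[13] == -0.5

    def test_baseline_weeks_excluded(self):
        b = Baseline(mean=10.0, sd=2.0, window=(9, 11), n=3)
        z = zscore_series(series({9: 8.0, 12: 10.0}), b)
        assert list(z.index) == [12]

    def test_degenerate_sd_errors(self):
        b = Baseline(mean=10.0, sd=0.0, window=(9, 11), n=3)
        with pytest.raises(DegenerateBaselineError):
            zscore_series(series({12: 10.0}), b)


class TestGroupOnset:
    @pytest.mark.parametrize("z,expected", [
        ({12: -0.2, 13: -0.6, 14: -1.1}, 13),   # first crossing
        ({12: -0.2, 13: -0.4, 14: -0.45}, None),  # never crossed
        ({13: -0.5}, 13),                        # boundary inclusive
    ])
    def test_first_crossing(self, z, expected):
        assert detect_group_onset(series(z)).onset_week == expected

    def test_empty_series_errors(self):
        with pytest.raises(ValueError, match="empty"):
            detect_group_onset(series({}))

    def test_sustain_requires_consecutive_weeks(self):
        z = series({12: -0.6, 13: -0.3, 14: -0.7, 15: -0.9})
        assert detect_group_onset(z, sustain=1).onset_week == 12
        assert detect_group_onset(z, sustain=2).onset_week == 14

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=8),
           st.lists(st.floats(0, 2), min_size=8, max_size=8))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_pointwise_lower_never_later(self, zvals, drops):
        weeks = range(12, 12 + len(zvals))
        z = pd.Series(zvals, index=weeks)
        lower = z - pd.Series(drops[:len(zvals)], index=weeks)
        w1 = detect_group_onset(z).onset_week
        w2 = detect_group_onset(lower).onset_week
        if w1 is not None:
            assert w2 is not None and w2 <= w1


class TestAnimalOnset:
    def base(self, mean=100.0):
        return Baseline(mean=mean, sd=5.0, window=(9, 11), n=3)

    @pytest.mark.parametrize("vals,expected", [
        ({12: 85.0, 13: 79.0, 14: 70.0}, 13),   # first value <= 80
        ({12: 85.0, 13: 81.0, 14: 82.0}, None),  # never 20% below
        ({12: 90.0, 13: 80.0}, 13),              # exactly 20% counts
    ])
    def test_relative_rule(self, vals, expected):
        call = detect_animal_onset(series(vals), self.base())
        assert call.onset_week == expected
        assert call.rule == "relative_20pct"

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError, match="onpositive"):
            detect_animal_onset(series({12: 1.0}), self.base(mean=0.0))

    def test_coincides_with_z_rule_when_sd_is_40pct_of_mean(self):
        # (x - m)/m <= -0.2  <=>  (x - m)/(0.4 m) <= -0.5
        mean = 50.0
        b = Baseline(mean=mean, sd=0.4 * mean, window=(9, 11), n=3)
        rng = np.random.default_rng(7)
        for _ in range(50):
            vals = series({w: rng.uniform(30, 60) for w in range(12, 19)})
            w_rel = detect_animal_onset(vals, b).onset_week
            w_z = detect_group_onset(zscore_series(vals, b)).onset_week
            assert w_rel == w_z


class TestExtrapolation:
    def test_linear_trend_anchored(self):
        weeks = range(9, 19)
        wt = pd.Series([1.0 + 0.02 * (w - 9) for w in weeks], index=weeks)
        b = Baseline(mean=1.01, sd=0.1, window=(9, 11), n=30)
        proj = extrapolate_weight_baseline(wt, b)
        assert proj.loc[18] == pytest.approx(1.01 + 0.02 * 8)
        assert proj.loc[10] == pytest.approx(1.01)

    def test_flat_trend_constant_projection(self):
        wt = pd.Series(2.0, index=range(9, 19))
        b = Baseline(mean=1.5, sd=0.1, window=(9, 11), n=30)
        assert (extrapolate_weight_baseline(wt, b) == 1.5).all()

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        weeks = np.arange(9, 19, dtype=float)
        y = 1.0 + 0.02 * weeks + rng.normal(0, 0.01, len(weeks))
        X = np.column_stack([np.ones_like(weeks), weeks])
        slope_oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        b = Baseline(mean=1.2, sd=0.1, window=(9, 11), n=30)
        proj = pd.Series(extrapolate_weight_baseline(pd.Series(y, index=weeks.astype(int)), b))
        fitted_slope = (proj.loc[18] - proj.loc[9]) / 9
        assert fitted_slope == pytest.approx(slope_oracle, rel=1e-12)

    def test_too_few_weeks_errors(self):
        b = Baseline(mean=1.0, sd=0.1, window=(9, 11), n=30)
        with pytest.raises(ValueError, match=">= 2"):
            extrapolate_weight_baseline(pd.Series({9: 1.0}), b)


class TestSidak:
    @pytest.mark.parametrize("p,m,expected", [
        (0.05, 1, 0.05),
        (0.0, 10, 0.0),
        (0.01, 10, 1 - 0.99 ** 10),   # ~0.09562
        (0.5, 50, 1.0),               # capped
    ])
    def test_closed_form(self, p, m, expected):
        assert sidak_adjust(p, m) == pytest.approx(expected)

    @pytest.mark.parametrize("p,m", [(-0.1, 2), (1.1, 2), (0.5, 0)])
    def test_domain_errors(self, p, m):
        with pytest.raises(ValueError):
            sidak_adjust(p, m)

    @given(st.floats(0, 1), st.integers(1, 40), st.integers(0, 10))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_and_dominates_raw(self, p, m, dm):
        adj = sidak_adjust(p, m)
        assert adj >= p - 1e-15
        assert sidak_adjust(p, m + dm) >= adj - 1e-15


class TestWeeklyComparison:
    def test_identical_groups_null(self):
        out = weekly_group_comparison({12: [3.0, 3.0]}, {12: [3.0, 3.0]})
        row = out.iloc[0]
        assert (row["t"], row["raw_p"], row["adj_p"]) == (0.0, 1.0, 1.0)

    def test_hand_evaluated_t(self):
        out = weekly_group_comparison({12: [4.0, 5.0, 6.0]}, {12: [1.0, 2.0, 3.0]})
        assert out.iloc[0]["t"] == pytest.approx(3.674, abs=1e-3)
        assert out.iloc[0]["raw_p"] == pytest.approx(0.0213, abs=2e-4)

    def test_family_size_is_number_of_tested_weeks(self):
        wt = {w: [4.0, 5.0, 6.0] for w in range(12, 19)}
        sod1 = {w: [1.0, 2.0, 3.0] for w in range(12, 19)}
        out = weekly_group_comparison(wt, sod1)
        # Sidak with m = 7: 1 - (1 - 0.0213)^7 ~ 0.140
        assert out["adj_p"].iloc[0] == pytest.approx(0.140, abs=2e-3)
        assert len(out) == 7

    def test_underpowered_week_skipped(self):
        out = weekly_group_comparison({12: [1.0], 13: [4.0, 5.0, 6.0]},
                                      {12: [1.0, 2.0], 13: [1.0, 2.0, 3.0]})
        assert list(out["week"]) == [13]
        # family shrinks to the single tested week
        assert out.iloc[0]["adj_p"] == pytest.approx(out.iloc[0]["raw_p"])
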