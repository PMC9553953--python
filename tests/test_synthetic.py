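"""Synthetic cohort generator: determinism, programmed means, recovery."""

import dataclasses

import pandas as pd
import pytest

from stringpull.config import ConfigError, RegionCoupling, SimConfig
from stringpull.experiments import modal_week, replicate_group_onsets
from stringpull.simulate import simulate_cohort, simulate_histology


def zero_noise_config(**overrides):
    base = dict(
        noise_sd={m: 0.0 for m in ("time_pulling_s", "time_hindlimbs_s", "length_pulled_cm")},
        animal_sd={m: 0.0 for m in ("time_pulling_s", "time_hindlimbs_s", "length_pulled_cm")},
        weight_animal_sd_g=0.0, weight_noise_sd_g=0.0)
    base.update(overrides)
    return SimConfig(**base)


class TestDeterminism:
    def test_identical_seed_identical_dataset(self):
        a, b = simulate_cohort(SimConfig(seed=11)), simulate_cohort(SimConfig(seed=11))
        pd.testing.assert_frame_equal(a.sessions, b.sessions)
        pd.testing.assert_frame_equal(a.weights, b.weights)
        pd.testing.assert_frame_equal(a.histology, b.histology)

    def test_different_seed_differs(self):
        a, b = simulate_cohort(SimConfig(seed=11)), simulate_cohort(SimConfig(seed=12))
        assert not a.sessions["time_pulling_s"].equals(b.sessions["time_pulling_s"])

    def test_standalone_histology_matches_embedded(self):
        cfg = SimConfig(seed=5)
        pd.testing.assert_frame_equal(simulate_histology(cfg),
                                      simulate_cohort(cfg).histology)


class TestProgrammedMeans:
    def test_zero_noise_wt_sessions_equal_baselines(self):
        ds = simulate_cohort(zero_noise_config())
        wt = ds.sessions[ds.sessions["genotype"] == "WT"]
        assert (wt["time_pulling_s"] == 30.0).all()
        assert (wt["time_hindlimbs_s"] == 20.0).all()
        assert (wt["length_pulled_cm"] == 80.0).all()

    def test_zero_noise_sod1_deficit_by_hand(self):
        # baseline 20 s, slope 0.5 SD/week with SD fixed at 2 s, onset week 12:
        # week 14 -> 20 - 0.5 * 2 * 2 = 18 s
        cfg = zero_noise_config(
            metric_baselines={"time_pulling_s": 20.0, "time_hindlimbs_s": 10.0,
                              "length_pulled_cm": 80.0},
            deficit_sd={"time_pulling_s": 2.0})
        ds = simulate_cohort(cfg)
        sod1 = ds.sessions[(ds.sessions["genotype"] == "SOD1")
                           & (ds.sessions["week"] == 14)]
        assert (sod1["time_pulling_s"] == 18.0).all()
        assert cfg.expected_metric_mean("SOD1", "time_pulling_s", 14) == 18.0

    def test_deficit_flat_before_onset(self):
        cfg = SimConfig()
        for metric in ("time_pulling_s", "time_hindlimbs_s"):
            for week in (9, 10, 11, 12):
                assert cfg.expected_deficit(metric, week) == 0.0

    def test_monotone_severity_in_slope(self):
        cfgs = [dataclasses.replace(SimConfig(), deficit_slope_sd_per_week=s)
                for s in (0.25, 0.5, 0.75, 1.0)]
        for week in range(12, 19):
            means = [c.expected_metric_mean("SOD1", "time_pulling_s", week)
                     for c in cfgs]
            assert means == sorted(means, reverse=True)

    def test_physical_truncation_under_heavy_noise(self):
        cfg = SimConfig(noise_sd={"time_pulling_s": 50.0, "time_hindlimbs_s": 50.0,
                                  "length_pulled_cm": 100.0}, seed=3)
        s = simulate_cohort(cfg).sessions
        assert (s["time_pulling_s"] >= 0).all() and (s["time_pulling_s"] <= 60).all()
        assert (s["length_pulled_cm"] >= 0).all()
        assert (s["time_hindlimbs_s"] <= s["time_pulling_s"]).all()


class TestHistologyGeneration:
    def test_zero_coupling_noise_wt_constant(self):
        cfg = SimConfig(histology_coupling={
            "M1": RegionCoupling(30.0, "time_pulling_s", 1.0, 0.0),
            "L5VH": RegionCoupling(12.0, "time_hindlimbs_s", 0.5, 0.0)})
        h = simulate_histology(cfg)
        wt_m1 = h[(h["genotype"] == "WT") & (h["region"] == "M1")]
        assert (wt_m1["mn_count"] == 30).all()

    def test_zero_noise_week19_half_of_week7(self):
        # slope chosen so the matched behavioral deficit at week 19 (behavior
        # week 18: 0.5 SD/wk * 5 s * 6 wk = 15 s) removes half the healthy count
        cfg = SimConfig(deficit_sd={"time_pulling_s": 5.0},
                        histology_coupling={
                            "M1": RegionCoupling(30.0, "time_pulling_s", 1.0, 0.0),
                            "L5VH": RegionCoupling(12.0, "time_hindlimbs_s", 0.0, 0.0)})
        h = simulate_histology(cfg)
        sod1_m1 = h[(h["genotype"] == "SOD1") & (h["region"] == "M1")]
        w7 = sod1_m1.loc[sod1_m1["week"] == 7, "mn_count"].mean()
        w19 = sod1_m1.loc[sod1_m1["week"] == 19, "mn_count"].mean()
        assert w19 == pytest.approx(w7 / 2)

    def test_group_sizes(self):
        h = simulate_histology(SimConfig())
        per_cell = h.groupby(["week", "region", "genotype"])["animal_id"].nunique()
        assert (per_cell == 6).all()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,field", [
        (dict(n_wt=0), "n_wt"),
        (dict(sessions_per_week=0), "sessions_per_week"),
        (dict(weeks=(18, 9)), "weeks"),
        (dict(deficit_onset_week=10), "deficit_onset_week"),
        (dict(noise_sd={"time_pulling_s": -1.0, "time_hindlimbs_s": 3.0,
                        "length_pulled_cm": 12.0}), "noise_sd"),
        (dict(weight_start_g=0.0), "weight_start_g"),
        (dict(sex_ratio=1.5), "sex_ratio"),
    ])
    def test_errors_name_offending_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs)


class TestRecovery:
    def test_modal_onset_recovers_programmed_week(self):
        # expected group z first reaches -0.5 one week after the week-12
        # deficit start; the mode over 50 replicate cohorts must land there
        df = replicate_group_onsets(SimConfig(), seeds=range(200, 250))
        for metric, grp in df.groupby("metric"):
            assert modal_week(grp["onset_week"]) == 13, metric
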