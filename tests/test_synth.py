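"""Generator tests: determinism, moment/correlation recovery, feasibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gaitwatch import synth
from gaitwatch.errors import ConfigError, GenerationError
from gaitwatch.params import (DRAWN_VARS, LAME_POOLED_MEANS, LAME_POOLED_SDS,
                              NONLAME_PARAMS, GroupParams)
from gaitwatch.segmentation import segment


def two_group_config(n_c=500, n_l=500, seed=0, **kwargs):
    lame = GroupParams(group_label="LI", n_cows=n_l,
                       means=dict(LAME_POOLED_MEANS),
                       sds=dict(LAME_POOLED_SDS),
                       nrs_probs={3.0: 1.0}, **kwargs)
    ctrl = dataclasses.replace(NONLAME_PARAMS, n_cows=n_c)
    return synth.SimConfig(groups=(ctrl, lame), seed=seed)


class TestCohort:
    def test_seeded_determinism(self):
        cfg = synth.default_config(seed=42)
        a = synth.cohort_to_frame(synth.simulate_cohort(cfg))
        b = synth.cohort_to_frame(synth.simulate_cohort(cfg))
        pd.testing.assert_frame_equal(a, b)
        c = synth.cohort_to_frame(
            synth.simulate_cohort(synth.default_config(seed=43)))
        assert not a.equals(c)

    def test_group_c_example_means_within_3_se(self):
        """Non-lame lying/standing time at n=500 lands within 3 SE."""
        cfg = two_group_config(n_c=500, n_l=10, seed=1)
        frame = synth.cohort_to_frame(synth.simulate_cohort(cfg))
        cows = frame[frame["group"] == "C"].groupby("cow_id").mean(
            numeric_only=True)
        assert abs(cows["lying_time"].mean() - 679.65) < 3 * 74.13 / np.sqrt(500)
        assert abs(cows["standing_time"].mean() - 718.97) < 3 * 74.4 / np.sqrt(500)

    def test_moment_recovery_all_variables(self):
        """Every sampled variable's group mean converges to its target.

        4-SE bound: with 26 variable-by-group checks a strict 3-SE bound
        would fail on ordinary fluctuations several percent of the time.
        """
        cfg = two_group_config(n_c=500, n_l=500, seed=7)
        frame = synth.cohort_to_frame(synth.simulate_cohort(cfg))
        cow_means = frame.groupby(["group", "cow_id"]).mean(numeric_only=True)
        for params in cfg.groups:
            sub = cow_means.loc[params.group_label]
            for name in DRAWN_VARS:
                se = params.sds[name] / np.sqrt(params.n_cows)
                if se == 0:
                    continue
                err = abs(sub[name].mean() - params.means[name])
                assert err < 4.0 * se + 0.5 * int(name in (
                    "lying_bouts", "walking_bouts", "strides")), name

    def test_time_budget_conservation(self):
        frame = synth.cohort_to_frame(
            synth.simulate_cohort(synth.default_config(seed=3)))
        total = frame["lying_time"] + frame["standing_time"] + frame["walking_time"]
        assert np.allclose(total, 1440.0, atol=1.0)
        counts = frame[["lying_bouts", "standing_bouts", "walking_bouts",
                        "strides"]]
        assert (counts >= 0).all().all()
        assert np.allclose(counts, counts.round())

    def test_sd_zero_gives_identical_cows(self):
        ctrl = dataclasses.replace(
            NONLAME_PARAMS, n_cows=5,
            sds={k: 0.0 for k in NONLAME_PARAMS.sds})
        cfg = synth.SimConfig(groups=(ctrl,), seed=0, day_sd_fraction=0.0)
        frame = synth.cohort_to_frame(synth.simulate_cohort(cfg))
        for name in ("eating_time", "lying_time", "strides"):
            assert frame[name].nunique() == 1

    def test_structural_bout_correlation_recovered(self):
        """standing ~ walking bouts come out strongly correlated (~0.98)."""
        from gaitwatch.group_stats import spearman_matrix
        cfg = two_group_config(n_c=300, n_l=300, seed=5)
        frame = synth.cohort_to_frame(synth.simulate_cohort(cfg))
        rho = spearman_matrix(frame, ["standing_bouts", "walking_bouts"]).iloc[0, 1]
        assert rho > 0.93

    def test_copula_correlation_recovery(self):
        """An explicit Spearman constraint is reproduced within 0.05."""
        from scipy.stats import spearmanr
        ctrl = dataclasses.replace(
            NONLAME_PARAMS, n_cows=600,
            correlations=[("eating_time", "ruminating_time", -0.6)])
        cfg = synth.SimConfig(groups=(ctrl,), seed=9, day_sd_fraction=0.0)
        frame = synth.cohort_to_frame(synth.simulate_cohort(cfg))
        cows = frame.groupby("cow_id").mean(numeric_only=True)
        rho = spearmanr(cows["eating_time"], cows["ruminating_time"]).statistic
        assert abs(rho - (-0.6)) < 0.05

    def test_invalid_params_rejected(self):
        bad = dataclasses.replace(
            NONLAME_PARAMS,
            means={**NONLAME_PARAMS.means, "lying_time": 1430.0,
                   "walking_time": 100.0})
        with pytest.raises(ConfigError):
            synth.SimConfig(groups=(bad,)).validate()
        with pytest.raises(ConfigError):
            synth.SimConfig(groups=(NONLAME_PARAMS,), days_per_cow=1).validate()


class TestDayFlags:
    def test_zero_and_certain_rates(self):
        cohort = synth.simulate_cohort(synth.default_config(seed=0))
        flags = synth.inject_day_flags(
            cohort, {"heat": 0.0, "insemination": 0.0, "ill": 0.0}, seed=1)
        assert (flags["flag"] == "ok").all()
        flags = synth.inject_day_flags(cohort, {"heat": 1.0}, seed=1)
        assert (flags["flag"] == "heat").all()

    def test_marginal_rate_within_binomial_ci(self):
        cfg = two_group_config(n_c=200, n_l=200, seed=2)
        cohort = synth.simulate_cohort(cfg)       # 400 cows x 3 days
        flags = synth.inject_day_flags(cohort, {"heat": 0.1}, seed=3)
        rate = (flags["flag"] == "heat").mean()
        assert 0.08 <= rate <= 0.12

    def test_reproducible_under_seed(self):
        cohort = synth.simulate_cohort(synth.default_config(seed=0))
        a = synth.inject_day_flags(cohort, seed=5)
        b = synth.inject_day_flags(cohort, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestEventStream:
    def targets(self, **over):
        base = {"lying_time": 720.0, "lying_bouts": 1.0, "walking_time": 40.0,
                "walking_bouts": 100.0, "strides": 1000.0,
                "stride_duration": 1800.0, "stride_distance": 130.0,
                "standing_bouts": 101.0}
        base.update(over)
        return base

    def test_round_trip_matches_targets(self):
        """Segmenting the stream reproduces the bout targets it encodes."""
        t = self.targets()
        result = segment(synth.simulate_event_stream(t, seed=1))
        assert len(result.lying_bouts) == 1
        assert len(result.walking_bouts) == 100
        assert len(result.standing_bouts) == 101
        assert result.lying_time_min == pytest.approx(720.0, abs=0.01)
        assert result.walking_time_min == pytest.approx(40.0, abs=0.01)
        assert result.counted_strides == 1000

    def test_round_trip_on_simulated_cohort_days(self):
        cohort = synth.simulate_cohort(synth.default_config(seed=8))
        for cow in cohort[::17]:
            t = cow.days[0]
            result = segment(synth.simulate_event_stream(t, seed=4))
            assert len(result.walking_bouts) == int(t["walking_bouts"])
            assert len(result.lying_bouts) == int(t["lying_bouts"])
            assert len(result.standing_bouts) == int(t["standing_bouts"])
            assert result.counted_strides == int(t["strides"])
            assert result.lying_time_min == pytest.approx(t["lying_time"],
                                                          rel=1e-6)
            assert result.walking_time_min == pytest.approx(t["walking_time"],
                                                            rel=1e-4)

    def test_zero_walking_means_no_strides(self):
        t = self.targets(walking_time=0.0, walking_bouts=0.0, strides=0.0,
                         standing_bouts=1.0)
        stream = synth.simulate_event_stream(t, seed=0)
        assert len(stream.strides) == 0

    def test_infeasible_targets_name_the_constraint(self):
        with pytest.raises(GenerationError, match="walking time too small"):
            synth.simulate_event_stream(
                self.targets(walking_time=10.0), seed=0)
        with pytest.raises(GenerationError, match="3 strides"):
            synth.simulate_event_stream(
                self.targets(strides=150.0, walking_time=6.0), seed=0)
        with pytest.raises(GenerationError, match="lying time too small"):
            synth.simulate_event_stream(
                self.targets(lying_time=1.0, lying_bouts=2.0), seed=0)

    def test_stream_determinism(self):
        t = self.targets()
        a = synth.simulate_event_stream(t, seed=11)
        b = synth.simulate_event_stream(t, seed=11)
        pd.testing.assert_frame_equal(a.posture, b.posture)
        pd.testing.assert_frame_equal(a.strides, b.strides)

    def test_walking_speed_near_group_target(self):
        """Lame-group targets realise a ~0.54 m/s derived walking speed."""
        t = dict(LAME_POOLED_MEANS)
        t["stride_distance"] = (t["walking_speed_calc"]
                                * t["stride_duration"] / 10.0)
        t["standing_bouts"] = t["lying_bouts"] + t["walking_bouts"]
        stream = synth.simulate_event_stream(t, seed=7)
        from gaitwatch.segmentation import summarize_hourly
        from gaitwatch.aggregation import daily_summary
        ds = daily_summary(summarize_hourly(stream))
        assert abs(ds["walking_speed_calc"] - 0.54) < 0.05


class TestHalterHourly:
    def test_weighted_means_and_sums_reproduced(self):
        t = {"eating_time": 378.6, "ruminating_time": 583.2,
             "eating_chews": 29270.0, "ruminating_chews": 40760.0,
             "bolus": 614.0, "chews_per_minute": 75.74,
             "chews_per_bolus": 65.87}
        hourly = synth.simulate_halter_hourly(t, seed=2)
        assert hourly["eating_time"].sum() == pytest.approx(378.6)
        assert hourly["bolus"].sum() == pytest.approx(614.0)
        w = hourly["ruminating_time"]
        cpm = (hourly["chews_per_minute"] * w).sum() / w.sum()
        assert cpm == pytest.approx(75.74, abs=1e-9)
        assert (hourly["eating_time"] + hourly["ruminating_time"] <= 60.0).all()
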