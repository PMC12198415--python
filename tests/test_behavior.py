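import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dgsomi import behavior as beh


def oracle_transitions(t, speed, dt, imm=0.5, run=3.0, min_imm=3.0, max_tr=3.0):
    """Exhaustive per-sample scan for running on/offsets (independent of the
    interval-based implementation)."""
    onsets, offsets = [], []
    n = len(speed)
    i = 0
    while i < n:
        if speed[i] < imm:
            j = i
            while j < n and speed[j] < imm:
                j += 1
            dur = (j - i) * dt
            if dur >= min_imm:
                if j < n and np.any(
                    speed[j : j + int(round(max_tr / dt)) + 1] >= run
                ):
                    onsets.append(t[j])
                lo = max(i - int(round(max_tr / dt)) - 1, 0)
                if i > 0 and np.any(speed[lo:i] >= run):
                    offsets.append(t[i])
            i = j
        else:
            i += 1
    return onsets, offsets


class TestSegmentMotion:
    def test_all_zero_speed_single_immobile_interval_no_transitions(self):
        t = np.arange(0, 10, 0.01)
        segs = beh.segment_motion(t, np.zeros_like(t))
        assert len(segs.intervals) == 1
        assert segs.intervals.iloc[0]["state"] == "immobile"
        assert len(segs.transitions) == 0

    def test_constant_running_no_onsets(self):
        t = np.arange(0, 10, 0.01)
        segs = beh.segment_motion(t, np.full_like(t, 10.0))
        assert len(segs.transitions) == 0

    def test_onset_time_is_first_sample_leaving_immobility(self):
        dt = 0.01
        t = np.arange(0, 10, dt)
        speed = np.where(t < 4.0, 0.0, np.clip((t - 4.0) * 5.0, 0, 5.0))
        segs = beh.segment_motion(t, speed)
        ons = segs.transitions[segs.transitions["kind"] == "onset"]
        assert len(ons) == 1
        # first sample with speed >= 0.5 cm/s on the ramp
        expected = t[np.flatnonzero(speed >= 0.5)[0]]
        assert ons.iloc[0]["t"] == pytest.approx(expected, abs=1e-9)

    def test_slow_ramp_does_not_qualify_as_onset(self):
        dt = 0.01
        t = np.arange(0, 20, dt)
        # reaches 3 cm/s only after 6 s, slower than the 3 s transition limit
        speed = np.where(t < 5.0, 0.0, np.clip((t - 5.0) * 0.5, 0, 10.0))
        segs = beh.segment_motion(t, speed)
        assert (segs.transitions["kind"] == "onset").sum() == 0

    def test_non_uniform_time_base_rejected(self):
        t = np.array([0.0, 0.01, 0.03, 0.04])
        with pytest.raises(ValueError, match="uniform"):
            beh.segment_motion(t, np.zeros(4))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dt = 0.05
        # random piecewise speed: alternating rest and run epochs
        parts = []
        for _ in range(rng.integers(2, 8)):
            dur = int(rng.integers(10, 120))
            level = rng.choice([0.0, 0.2, 1.5, 5.0, 12.0])
            parts.append(np.full(dur, level))
        speed = np.concatenate(parts)
        t = np.arange(speed.size) * dt
        segs = beh.segment_motion(t, speed)
        ons, offs = oracle_transitions(t, speed, dt)
        got_on = segs.transitions.loc[segs.transitions["kind"] == "onset", "t"]
        got_off = segs.transitions.loc[segs.transitions["kind"] == "offset", "t"]
        np.testing.assert_allclose(np.sort(got_on), np.sort(ons), atol=1e-9)
        np.testing.assert_allclose(np.sort(got_off), np.sort(offs), atol=1e-9)

    def test_intervals_partition_the_trace(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 50, 0.02)
        speed = np.abs(rng.normal(2, 3, t.size))
        segs = beh.segment_motion(t, speed)
        iv = segs.intervals
        assert iv.iloc[0]["start"] == t[0]
        np.testing.assert_allclose(iv["end"].iloc[:-1], iv["start"].iloc[1:])


def _flat_behavior(T=300.0, speed=10.0):
    t = np.arange(0, T, 0.01)
    return pd.DataFrame({"t": t, "position": (t * speed) % 400,
                         "speed": np.full(t.size, speed)})


class TestZoneRates:
    def test_post_only_licks(self):
        b = _flat_behavior()
        rewards = np.array([50.0, 100.0, 150.0])
        licks = np.concatenate([rewards + 0.5, rewards + 1.0])
        zr = beh.zone_rates(licks, b, rewards)
        assert (zr["lick_baseline"] == 0).all()
        assert (zr["lick_pre"] == 0).all()
        assert (zr["lick_post"] == 1.0).all()

    def test_homogeneous_licking_equal_zone_rates(self):
        b = _flat_behavior()
        licks = np.arange(0.25, 300, 0.5)  # exactly 2 Hz
        zr = beh.zone_rates(licks, b, np.array([50.0, 100.0]))
        for z in ("baseline", "pre", "post"):
            np.testing.assert_allclose(zr[f"lick_{z}"], 2.0)

    def test_clipped_window_flagged(self):
        b = _flat_behavior(T=30)
        zr = beh.zone_rates(np.array([]), b, np.array([3.0, 20.0]))
        assert zr.iloc[0]["clipped"] and not zr.iloc[1]["clipped"]

    def test_expert_session_pre_exceeds_baseline_most_laps(self, expert_session):
        session, _ = expert_session
        zr = beh.zone_rates(session.event_times("lick"), session.behavior,
                            session.reward_times)
        frac = np.mean(zr["lick_pre"] > zr["lick_baseline"])
        assert frac >= 0.7


class TestClassifyPerformance:
    def _zr(self, lick_pre, lick_base, sp_pre, sp_base):
        n = len(lick_pre)
        return pd.DataFrame(
            {"lick_pre": lick_pre, "lick_baseline": lick_base,
             "lick_post": np.zeros(n), "speed_pre": sp_pre,
             "speed_baseline": sp_base, "speed_post": np.zeros(n)}
        )

    def test_expert_ground_truth_sessions(self, expert_session, nonexpert_session):
        for (session, gt) in (expert_session, nonexpert_session):
            zr = beh.zone_rates(session.event_times("lick"), session.behavior,
                                session.reward_times)
            v = beh.classify_performance(zr)
            assert v["performance"] == gt["performance"]

    def test_lick_increase_alone_is_not_expert(self):
        rng = np.random.default_rng(0)
        n = 40
        zr = self._zr(rng.poisson(8, n) / 2, rng.poisson(1, n) / 2,
                      20 + rng.normal(0, 0.5, n), 20 + rng.normal(0, 0.5, n))
        v = beh.classify_performance(zr)
        assert v["performance"] == "nonexpert"
        assert v["p_lick"] < 0.05 and v["p_speed"] > 0.05

    def test_flat_everything_is_not_expert(self):
        rng = np.random.default_rng(1)
        n = 40
        zr = self._zr(rng.poisson(1, n) / 2, rng.poisson(1, n) / 2,
                      20 + rng.normal(0, 0.5, n), 20 + rng.normal(0, 0.5, n))
        assert beh.classify_performance(zr)["performance"] == "nonexpert"

    def test_too_few_laps_refused(self):
        zr = self._zr(np.ones(5), np.zeros(5), np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match=">= 10"):
            beh.classify_performance(zr)

    def test_type_one_error_on_null_sessions(self):
        # no modulation anywhere: expert verdicts must be rare
        rng = np.random.default_rng(2)
        n_expert = 0
        reps = 400
        for _ in range(reps):
            n = 30
            zr = self._zr(rng.poisson(2, n) / 2, rng.poisson(2, n) / 2,
                          20 + rng.normal(0, 1, n), 20 + rng.normal(0, 1, n))
            if beh.classify_performance(zr)["performance"] == "expert":
                n_expert += 1
        assert n_expert / reps <= 0.075


class TestPerformanceScore:
    def test_all_and_none_anticipatory(self):
        zr = pd.DataFrame({"lick_pre": [2.0, 3.0], "lick_baseline": [0.5, 1.0]})
        assert beh.performance_score(zr) == 1.0
        zr = pd.DataFrame({"lick_pre": [0.1, 0.2], "lick_baseline": [0.5, 1.0]})
        assert beh.performance_score(zr) == 0.0

    def test_binomial_spread_at_known_anticipation_probability(self):
        rng = np.random.default_rng(3)
        n = 100
        antic = rng.uniform(size=n) < 0.75
        zr = pd.DataFrame({"lick_pre": np.where(antic, 2.0, 0.0),
                           "lick_baseline": np.full(n, 1.0)})
        score = beh.performance_score(zr)
        assert abs(score - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)


class TestLickLapTrend:
    def test_perfect_linear_trend(self):
        res = beh.lick_lap_trend(np.arange(20.0))
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] < 1e-3

    def test_constant_rates_flagged(self):
        res = beh.lick_lap_trend(np.full(10, 2.0))
        assert res["degenerate"] and res["r"] == 0.0

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(4)
        y = 5.0 - 0.1 * np.arange(30) + rng.normal(0, 0.5, 30)
        res = beh.lick_lap_trend(y)
        x = np.arange(30.0)
        A = np.column_stack([np.ones(30), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert res["slope"] == pytest.approx(beta[1], abs=1e-10)
        assert res["slope"] < 0

    def test_null_calibration_of_p_value(self):
        rng = np.random.default_rng(5)
        hits = sum(
            beh.lick_lap_trend(rng.normal(size=40))["p"] < 0.05 for _ in range(500)
        )
        assert abs(hits / 500 - 0.05) < 0.03
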