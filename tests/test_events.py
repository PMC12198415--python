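import numpy as np
import pandas as pd
import pytest

from dgsomi import events as ev
from dgsomi.synth import generate_spike_train
from dgsomi.rng import child_rng
from conftest import poisson_train


class TestAlign:
    def test_unit_firing_only_at_event_time(self):
        events = np.array([10.0, 20.0, 30.0])
        a = ev.align(events + 0.001, events)
        j = np.searchsorted(a.bin_edges_s, 0.001) - 1
        assert a.counts.sum() == 3
        assert (a.counts[:, j] == 1).all()

    def test_matches_brute_force_histogram(self):
        rng = np.random.default_rng(0)
        st = np.sort(rng.uniform(0, 100, 2000))
        events = np.array([20.0, 50.0, 80.0])
        a = ev.align(st, events)
        for k, e in enumerate(events):
            expected = np.histogram(st - e, bins=a.bin_edges_s)[0]
            np.testing.assert_array_equal(a.counts[k], expected)

    def test_edge_events_dropped_and_flagged(self):
        a = ev.align(np.array([5.0]), np.array([2.0, 50.0]), (-5, 5), 0.1,
                     recording_end_s=60.0)
        assert a.event_times.size == 1
        assert any("dropped_1" in f for f in a.flags)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            ev.align(np.array([1.0]), np.array([]))

    def test_homogeneous_poisson_flat_psth(self):
        rng = np.random.default_rng(1)
        st = poisson_train(20.0, 2000.0, rng)
        events = np.arange(10.0, 1990.0, 10.0)
        a = ev.align(st, events)
        mean_counts = a.counts.mean(axis=0)
        se = np.sqrt(2.0 / a.counts.shape[0])  # Poisson mean 2 per bin
        assert np.all(np.abs(mean_counts - 2.0) < 3 * se + 0.05)

    def test_zscore_normalizes_full_matrix(self):
        rng = np.random.default_rng(2)
        a = ev.align(np.sort(rng.uniform(0, 100, 500)), np.array([30.0, 60.0]))
        z = a.zscore()
        assert z.counts.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.counts.std() == pytest.approx(1.0, abs=1e-9)

    def test_smoothing_only_along_time(self):
        counts = np.zeros((4, 100))
        counts[2, 50] = 10.0
        a = ev.AlignedActivity(counts, np.arange(-5, 5.01, 0.1), np.arange(4))
        sm = a.smooth()
        assert sm.counts[2].sum() == pytest.approx(10.0, rel=1e-6)
        assert sm.counts[1].sum() == 0  # nothing leaks across trials
        assert sm.counts[2, 50] < 10.0


class TestRewardModulation:
    def test_generator_profiles_recovered(self, expert_session):
        session, gt = expert_session
        gtu = pd.DataFrame(gt["units"]).set_index("unit_id")
        exp_map = {"predictive": "anticipatory", "consumption": "non-anticipatory",
                   "suppressed": "non-anticipatory", "none": "unmodulated"}
        errors = 0
        for u in session.units:
            m = ev.reward_modulation(u.spike_times, session.reward_times)
            if m["classification"] != exp_map[gtu.loc[u.unit_id, "reward_profile"]]:
                errors += 1
        assert errors <= 3

    def test_consumption_cell_post_up_only(self):
        rng = child_rng(5, "c")
        rewards = np.arange(20.0, 620.0, 12.0)
        dt = 0.005
        t = np.arange(0, 640, dt)
        rate = np.full(t.size, 6.0)
        for r in rewards:
            rate *= 1 + 2.0 * np.exp(-0.5 * ((t - r - 1.2) / 0.4) ** 2)
        st = generate_spike_train(rate, dt, rng)
        m = ev.reward_modulation(st, rewards)
        assert m["post_direction"] == "up"
        assert m["classification"] == "non-anticipatory"

    def test_too_few_trials_refused(self):
        with pytest.raises(ValueError, match=">= 10"):
            ev.reward_modulation(np.arange(100.0), np.array([10.0, 20.0]))

    def test_null_cells_calibrate_to_alpha(self):
        rng = np.random.default_rng(6)
        rewards = np.arange(20.0, 500.0, 12.0)
        hits_pre = 0
        reps = 200
        for _ in range(reps):
            st = poisson_train(5.0, 510.0, rng)
            m = ev.reward_modulation(st, rewards)
            hits_pre += m["pre_direction"] != "none"
        assert abs(hits_pre / reps - 0.05) < 0.045


class TestDelayToMaxChange:
    def _bump_cell(self, peak_s, seed=0, gain=3.0, n_trials=30):
        rng = child_rng(seed, "d")
        rewards = np.arange(20.0, 20.0 + 12.0 * n_trials, 12.0)
        dt = 0.005
        t = np.arange(0, rewards[-1] + 20, dt)
        rate = np.full(t.size, 8.0)
        for r in rewards:
            rate *= 1 + (gain - 1) * np.exp(-0.5 * ((t - r - peak_s) / 0.4) ** 2)
        st = generate_spike_train(rate, dt, rng)
        return ev.align(st, rewards)

    @pytest.mark.parametrize("peak", [-0.1, 1.2])
    def test_recovers_generator_peak_within_one_bin(self, peak):
        delays = [
            ev.delay_to_max_change(self._bump_cell(peak, seed=s)) for s in range(3)
        ]
        assert abs(np.median(delays) - peak) <= 0.1

    def test_tie_breaks_to_earliest_bin(self):
        counts = np.zeros((5, 100))
        counts[:, 40] = 5.0  # bump at -1 s
        counts[:, 60] = 5.0  # equal bump at +1 s
        a = ev.AlignedActivity(counts, -5 + 0.1 * np.arange(101), np.arange(5))
        d = ev.delay_to_max_change(a)
        assert d < 0

    def test_flat_trace_rejected(self):
        counts = np.full((12, 100), 3.0)
        a = ev.AlignedActivity(counts, -5 + 0.1 * np.arange(101), np.arange(12))
        with pytest.raises(ValueError, match="modulation|constant"):
            ev.delay_to_max_change(a)


class TestOnOffClassification:
    def _transition_cell(self, kind, seed=0, n_trans=20):
        rng = child_rng(seed, "oo")
        onsets = np.arange(20.0, 20.0 + 15.0 * n_trans, 15.0)
        offsets = onsets + 7.0
        dt = 0.005
        t = np.arange(0, offsets[-1] + 20, dt)
        moving = np.zeros(t.size, bool)
        for a, b in zip(onsets, offsets):
            moving |= (t >= a) & (t < b)
        hi, lo = (12.0, 3.0) if kind == "OFF" else (3.0, 12.0)
        rate = np.where(moving, lo, hi)
        st = generate_spike_train(rate, dt, rng)
        return st, onsets, offsets

    @pytest.mark.parametrize("kind", ["OFF", "ON"])
    def test_generator_cells_recovered(self, kind):
        st, onsets, offsets = self._transition_cell(kind)
        out = ev.onoff_classify(st, onsets, offsets)
        assert out["classification"] == kind

    def test_unmodulated_cells_mostly_non(self):
        rng = np.random.default_rng(7)
        onsets = np.arange(20.0, 320.0, 15.0)
        offsets = onsets + 7.0
        n_non = 0
        reps = 100
        for _ in range(reps):
            st = poisson_train(8.0, 340.0, rng)
            if ev.onoff_classify(st, onsets, offsets)["classification"] == "NON":
                n_non += 1
        assert n_non / reps >= 0.9

    def test_too_few_transitions_flagged_non(self):
        out = ev.onoff_classify(np.arange(100.0), np.array([10.0]), np.array([20.0]))
        assert out["classification"] == "NON"
        assert "too_few_transitions" in out["flags"]


class TestSpeedRegression:
    def _session_like(self, T=400.0, seed=0):
        rng = child_rng(seed, "sp")
        t = np.arange(0, T, 0.01)
        speed = 10 + 8 * np.sin(2 * np.pi * t / 40.0)
        return pd.DataFrame({"t": t, "position": (t * 10) % 400, "speed": speed})

    def test_exact_linear_rate_recovered(self):
        b = self._session_like()
        # deterministic spikes with rate = 20 + 5 * speed (high rate keeps
        # per-bin count quantization small relative to the speed signal)
        dt = 0.001
        tt = np.arange(0, 400, dt)
        sp = np.interp(tt, b["t"], b["speed"])
        rate = 20 + 5.0 * sp
        # thinning-free train: cumulative-intensity inversion
        c = np.cumsum(rate * dt)
        st = np.interp(np.arange(1.0, c[-1], 1.0), c, tt)
        res = ev.speed_regression(st, b)
        assert res["slope"] == pytest.approx(5.0, abs=0.2)
        assert res["r"] > 0.95

    def test_matches_normal_equation_oracle(self):
        rng = child_rng(1, "sp2")
        b = self._session_like(seed=1)
        dt = 0.005
        tt = np.arange(0, 400, dt)
        sp = np.interp(tt, b["t"], b["speed"])
        st = generate_spike_train(2 + 0.3 * sp, dt, rng)
        res = ev.speed_regression(st, b, bin_s=0.1)
        edges = np.arange(0.0, 400.0, 0.1)
        idx = np.clip(np.searchsorted(edges, b["t"], side="right") - 1, 0,
                      edges.size - 2)
        x = np.bincount(idx, weights=b["speed"]) / np.bincount(idx)
        y = np.histogram(st, bins=edges)[0] / 0.1
        A = np.column_stack([np.ones(x.size), x])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert res["slope"] == pytest.approx(beta[1], abs=1e-10)

    def test_constant_speed_degenerate(self):
        t = np.arange(0, 200, 0.01)
        b = pd.DataFrame({"t": t, "position": (t * 5) % 400,
                          "speed": np.full(t.size, 5.0)})
        res = ev.speed_regression(np.arange(1.0, 199.0), b)
        assert res["degenerate"] and res["r"] == 0.0

    def test_steady_state_restriction_drops_slow_bins(self):
        b = self._session_like()
        st = np.arange(1.0, 399.0, 0.5)
        full = ev.speed_regression(st, b, steady_state_only=False)
        steady = ev.speed_regression(st, b, steady_state_only=True)
        assert steady["n_bins"] < full["n_bins"]


class TestSensoryResponse:
    def _stims(self):
        kinds = ["stim_airpuff", "stim_visual", "stim_sound"]
        rows = []
        for i, k in enumerate(kinds):
            on = 100.0 * i + 3.0 * np.arange(20)
            rows.append(pd.DataFrame({"t": on + 5.0, "kind": k, "duration": 0.5}))
        return pd.concat(rows, ignore_index=True)

    def test_airpuff_driven_cell(self):
        stims = self._stims()
        rng = child_rng(2, "sens")
        dt = 0.005
        t = np.arange(0, 320, dt)
        rate = np.full(t.size, 4.0)
        for _, row in stims[stims["kind"] == "stim_airpuff"].iterrows():
            rate[(t >= row["t"]) & (t < row["t"] + 0.5)] = 20.0
        st = generate_spike_train(rate, dt, rng)
        out = ev.sensory_response(st, stims)
        assert out["stim_airpuff"]["direction"] == "up"
        assert out["stim_visual"]["direction"] == "none"
        assert out["stim_sound"]["direction"] == "none"

    def test_silent_cell_all_none(self):
        out = ev.sensory_response(np.array([1.0]), self._stims())
        assert all(v["direction"] == "none" for v in out.values())

    def test_sparse_modality_skipped(self):
        stims = pd.DataFrame({"t": [10.0, 20.0], "kind": "stim_visual",
                              "duration": 0.5})
        out = ev.sensory_response(np.arange(50.0), stims)
        assert out["stim_visual"]["direction"] == "skipped"


class TestLapActivityCorrelation:
    def test_identical_lap_profiles_correlate_perfectly(self):
        profile = np.sin(np.linspace(0, 3, 40)) + 2
        counts = np.tile(profile, (10, 1))
        a = ev.AlignedActivity(counts, np.linspace(-2, 2, 41), np.arange(10))
        out = ev.lap_activity_correlation(a, np.arange(5), np.arange(5, 10))
        assert out["mean_r"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_laps_near_zero(self):
        rng = np.random.default_rng(8)
        rs = []
        for _ in range(100):
            counts = rng.normal(5, 1, (8, 40))
            a = ev.AlignedActivity(counts, np.linspace(-2, 2, 41), np.arange(8),
                                   smoothed=True)
            rs.append(ev.lap_activity_correlation(a, np.arange(4),
                                                  np.arange(4, 8))["mean_r"])
        assert abs(np.mean(rs)) < 3 * np.std(rs) / 10

    def test_modulation_change_reduces_cross_group_correlation(self):
        # laps before the switch share one profile, laps after another:
        # within-group correlation must exceed across-group correlation,
        # mirroring reward-translocation analyses
        rng = np.random.default_rng(9)
        p1 = np.exp(-0.5 * ((np.linspace(-2, 2, 40) + 0.5) / 0.4) ** 2)
        p2 = np.exp(-0.5 * ((np.linspace(-2, 2, 40) - 1.0) / 0.4) ** 2)
        counts = np.vstack([p1 + rng.normal(0, 0.1, 40) for _ in range(5)]
                           + [p2 + rng.normal(0, 0.1, 40) for _ in range(5)])
        a = ev.AlignedActivity(counts, np.linspace(-2, 2, 41), np.arange(10))
        within = ev.lap_activity_correlation(a, np.arange(5), np.arange(5))
        across = ev.lap_activity_correlation(a, np.arange(5), np.arange(5, 10))
        assert within["mean_r"] > across["mean_r"]

    def test_all_constant_flagged_nan(self):
        counts = np.ones((6, 40))
        a = ev.AlignedActivity(counts, np.linspace(-2, 2, 41), np.arange(6))
        out = ev.lap_activity_correlation(a, np.arange(3), np.arange(3, 6))
        assert np.isnan(out["mean_r"]) and "all_constant" in out["flags"]
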