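import numpy as np
import pytest

from dgsomi import decoder as dec
from dgsomi.rng import child_rng
from conftest import poisson_train


def _step_cell(rng, n_trials=30, base=5.0, gain=2.0, isi=20.0):
    """Poisson cell whose rate steps to gain x base during the 1.5 s before
    each reward; returns (spike_times, reward_times)."""
    rewards = 10.0 + isi * np.arange(n_trials)
    T = rewards[-1] + 10.0
    spikes = [poisson_train(base, T, rng)]
    extra = base * (gain - 1.0)
    for r in rewards:
        n = rng.poisson(extra * 1.5)
        spikes.append(np.sort(rng.uniform(r - 1.5, r, n)))
    return np.sort(np.concatenate(spikes)), rewards


class TestKdeRate:
    def test_single_spike_integrates_to_one(self):
        grid, lam = dec.kde_rate(np.array([0.0]), 1, (-1.5, 1.5), floor_hz=0.0)
        assert np.trapezoid(lam, grid) == pytest.approx(1.0, rel=0.02)

    def test_matches_direct_gaussian_sum_oracle(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(-1.5, 1.5, 40)
        a, b = -1.5, 1.5
        grid, lam = dec.kde_rate(s, 4, (a, b), floor_hz=0.0)
        h = 0.2
        src = np.concatenate([s, 2 * a - s, 2 * b - s])
        expected = np.array([
            np.sum(np.exp(-0.5 * ((g - src) / h) ** 2)) / (np.sqrt(2 * np.pi) * h * 4)
            for g in grid
        ])
        np.testing.assert_allclose(lam, expected, atol=1e-10)

    def test_homogeneous_training_data_recovers_rate(self):
        rng = np.random.default_rng(1)
        n_trials = 200
        s = rng.uniform(-1.5, 1.5, rng.poisson(5.0 * 3.0 * n_trials))
        grid, lam = dec.kde_rate(np.sort(s), n_trials, (-1.5, 1.5))
        inner = (grid > -1.0) & (grid < 1.0)
        se = np.sqrt(5.0 / (n_trials * 3.0)) * 3
        assert np.all(np.abs(lam[inner] - 5.0) < 3 * se + 0.3)

    def test_integral_matches_mean_training_count(self):
        rng = np.random.default_rng(2)
        s = np.sort(rng.uniform(-4.25, -1.5, 300))
        grid, lam = dec.kde_rate(s, 10, (-4.25, -1.5), floor_hz=0.0)
        integral = lam.sum() * 0.05
        assert integral == pytest.approx(300 / 10, rel=0.05)

    def test_zero_spikes_floor_rate(self):
        grid, lam = dec.kde_rate(np.array([]), 5, (-1.5, 1.5))
        np.testing.assert_allclose(lam, 0.1)


class TestLoglik:
    def test_zero_counts_closed_form(self):
        lam = np.full(30, 4.0)  # 4 Hz on a 0.05 s grid
        counts = np.zeros(6)  # 6 bins of 0.25 s
        # sum over bins of -lam*dt = -6 * 1.0
        assert dec.loglik(counts, lam, 0.05) == pytest.approx(-6.0)

    def test_matched_counts_maximize_over_rate_scalings(self):
        lam = np.full(60, 8.0)
        counts = np.full(6, 2.0)  # equals lam * 0.25
        best = dec.loglik(counts, lam, 0.05)
        for scale in (0.5, 0.8, 1.25, 2.0):
            assert dec.loglik(counts, lam * scale, 0.05) < best

    def test_equals_direct_summation(self):
        from scipy.special import gammaln
        rng = np.random.default_rng(3)
        lam = rng.uniform(1, 10, 40)
        counts = rng.poisson(2, 8).astype(float)
        mu = lam.reshape(8, 5).mean(axis=1) * 0.25
        expected = np.sum(counts * np.log(mu) - mu - gammaln(counts + 1))
        assert dec.loglik(counts, lam, 0.05) == pytest.approx(expected, abs=1e-10)


class TestDecodeSingle:
    def test_unmodulated_cell_at_chance(self):
        rng = child_rng(0, "chance")
        accs = []
        for k in range(20):
            st, rewards = _step_cell(rng, gain=1.0)
            res = dec.decode_single(st, rewards, [1.5], n_shuffles=50, seed=k)
            accs.append(res.accuracy[1.5])
        mean = np.mean(accs)
        assert abs(mean - 0.5) < 3 * np.sqrt(0.25 / (20 * 120))

    def test_step_modulated_cell_significant(self):
        rng = child_rng(1, "step")
        st, rewards = _step_cell(rng, gain=2.0)
        res = dec.decode_single(st, rewards, [1.5], n_shuffles=200, seed=1)
        assert res.accuracy[1.5] > 0.6
        assert res.significant[1.5]
        assert res.min_significant_L == 1.5

    def test_deterministic_rates_perfect_accuracy(self):
        # expectation window packed with spikes, baseline silent
        rewards = 10.0 + 20.0 * np.arange(20)
        st = np.sort(np.concatenate(
            [r - 1.5 + 0.05 + 0.1 * np.arange(15) for r in rewards]
        ))
        res = dec.decode_single(st, rewards, [1.5], n_shuffles=50, seed=0)
        assert res.accuracy[1.5] == 1.0

    def test_window_exceeding_class_period_skipped(self):
        rng = child_rng(2, "skip")
        st, rewards = _step_cell(rng)
        res = dec.decode_single(st, rewards, [5.0], n_shuffles=10, seed=0)
        assert res.accuracy == {}
        assert any("skipped" in f for f in res.flags)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match=">= 6"):
            dec.decode_single(np.arange(10.0), np.array([5.0, 10.0]), [0.5])

    def test_accuracy_monotone_in_rate_separation(self):
        rng = child_rng(3, "mono")
        means = []
        for gain in (1.0, 1.5, 2.0, 3.0):
            accs = []
            for k in range(25):
                st, rewards = _step_cell(rng, gain=gain)
                res = dec.decode_single(st, rewards, [1.5], n_shuffles=1, seed=k)
                accs.append(res.accuracy[1.5])
            means.append(np.mean(accs))
        assert means[0] < means[-1]
        assert all(b >= a - 0.03 for a, b in zip(means, means[1:]))

    def test_shuffle_null_centered_at_chance(self):
        rng = child_rng(4, "null")
        st, rewards = _step_cell(rng, gain=1.0)
        res = dec.decode_single(st, rewards, [0.5, 1.5, 2.5], n_shuffles=300,
                                seed=4)
        for L, q in res.null_quantile.items():
            assert 0.5 < q < 0.75  # 99th percentile of a chance-level binomial


class TestDecodePopulation:
    def test_single_cell_subset_consistent_with_decode_single(self):
        rng = child_rng(5, "pop1")
        st, rewards = _step_cell(rng, gain=2.0)
        single = dec.decode_single(st, rewards, [1.5], n_shuffles=1, seed=7)
        pop = dec.decode_population([st], rewards, 1.5, subset_sizes=[1],
                                    n_shuffles=1, seed=7)
        assert pop["accuracy_vs_n"][1] == pytest.approx(single.accuracy[1.5])

    def test_population_beats_best_single_cell(self):
        rng = child_rng(6, "pop")
        cells, rewards = [], None
        for _ in range(10):
            st, rewards = _step_cell(child_rng(int(rng.integers(1 << 30)), "c"),
                                     gain=1.5)
            cells.append(st)
        singles = [
            dec.decode_single(c, rewards, [1.5], n_shuffles=1, seed=0).accuracy[1.5]
            for c in cells
        ]
        pop = dec.decode_population(cells, rewards, 1.5, subset_sizes=[10],
                                    n_shuffles=1, seed=0)
        assert pop["accuracy_vs_n"][10] >= max(singles) - 0.05

    def test_oversized_subset_clipped(self):
        rng = child_rng(7, "clip")
        st, rewards = _step_cell(rng)
        pop = dec.decode_population([st], rewards, 1.5, subset_sizes=[5],
                                    n_shuffles=1, seed=0)
        assert any("clipped" in f for f in pop["flags"])


class TestResidualizedDecode:
    def test_zero_predictions_match_plain_population_decoding(self):
        rng = child_rng(8, "res")
        cells, rewards = [], None
        for _ in range(4):
            st, rewards = _step_cell(child_rng(int(rng.integers(1 << 30)), "c"),
                                     gain=2.0)
            cells.append(st)
        n_bins = int(round(5.75 / 0.25))
        zero_pred = [np.zeros((rewards.size, n_bins)) for _ in cells]
        res = dec.residualized_decode(cells, rewards, zero_pred, 1.5,
                                      n_shuffles=50, seed=0)
        assert res.accuracy[1.5] > 0.8

    def test_speed_driven_cell_drops_to_chance_after_residualization(self):
        # the cell's pre-reward elevation is entirely "speed-predicted":
        # subtracting the prediction must abolish decodable structure
        rng = child_rng(9, "res2")
        st, rewards = _step_cell(rng, gain=2.5, n_trials=40)
        n_bins = int(round(5.75 / 0.25))
        centers = -4.25 + 0.25 * (np.arange(n_bins) + 0.5)
        pred = np.tile(5.0 * 1.5 * ((centers >= -1.5) & (centers < 0.0)),
                       (rewards.size, 1))
        res = dec.residualized_decode([st], rewards, [pred], 1.5,
                                      n_shuffles=50, seed=1)
        plain = dec.residualized_decode(
            [st], rewards, [np.zeros_like(pred)], 1.5, n_shuffles=50, seed=1
        )
        assert res.accuracy[1.5] < plain.accuracy[1.5] - 0.2

    def test_missing_fits_skipped_with_flag(self):
        rng = child_rng(10, "res3")
        st, rewards = _step_cell(rng)
        n_bins = int(round(5.75 / 0.25))
        res = dec.residualized_decode(
            [st, st], rewards, [None, np.zeros((rewards.size, n_bins))], 1.5,
            n_shuffles=10, seed=0,
        )
        assert any("skipped_no_fit" in f for f in res.flags)
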