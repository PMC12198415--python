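"""Maximum-likelihood decoding of reward anticipation.

Two class periods are defined around each reward delivery: a *baseline*
period ending 1.5 s before delivery and an *expectation* period from 1.5 s
before until 1.5 s after delivery.  Per cell and class, an instantaneous
firing-rate model is estimated by Gaussian kernel density estimation
(bandwidth 200 ms, reflected at the window edges, normalized to Hz) from the
training trials' spike times.  A held-out spike-count pattern — one window
of length L anchored at the start of each class period — is classified by
the larger time-resolved Poisson count log-likelihood under the two rate
models; cross-validation is 2-fold over even versus odd trials.

Accuracy significance uses label shuffles of the held-out patterns (the
fitted rate models are kept fixed), compared at the 99th percentile.
Population decoding sums log-likelihoods over cells before the argmax; the
residualized variant first subtracts each cell's GLM-predicted speed and
acceleration modulation from the binned counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .rng import child_rng

__all__ = [
    "RateModel",
    "DecodeResult",
    "kde_rate",
    "loglik",
    "decode_single",
    "decode_population",
    "residualized_decode",
]

CLASSES = ("baseline", "expectation")


def kde_rate(
    rel_spike_times: np.ndarray,
    n_trials: int,
    window_s: tuple[float, float],
    bandwidth_s: float = 0.2,
    grid_s: float = 0.05,
    floor_hz: float = 0.1,
):
    """Gaussian-KDE firing rate (Hz) on a grid over ``window_s``.

    ``rel_spike_times`` are spike times relative to the event, pooled over
    ``n_trials`` training trials; each spike contributes a normal kernel of
    SD ``bandwidth_s`` whose mass is reflected at the window edges, so the
    rate integrates to the mean training spike count per trial.  Zero
    training spikes yield the floor rate.
    """
    a, b = window_s
    grid = a + grid_s * (np.arange(int(round((b - a) / grid_s))) + 0.5)
    s = np.asarray(rel_spike_times, dtype=float)
    s = s[(s >= a) & (s < b)]
    if s.size == 0 or n_trials == 0:
        return grid, np.full(grid.size, floor_hz)
    # reflected-boundary correction: mirror spikes about both edges
    src = np.concatenate([s, 2 * a - s, 2 * b - s])
    d = grid[:, None] - src[None, :]
    lam = np.exp(-0.5 * (d / bandwidth_s) ** 2).sum(axis=1) / (
        np.sqrt(2 * np.pi) * bandwidth_s * n_trials
    )
    return grid, np.maximum(lam, floor_hz)


def loglik(
    counts: np.ndarray, lam_hz: np.ndarray, grid_s: float, bin_s: float = 0.25
) -> float:
    """Time-resolved Poisson count log-likelihood.

    ``counts`` are spike counts in consecutive bins of ``bin_s``; ``lam_hz``
    is the rate model on its finer grid (``grid_s``), averaged per bin.
    Non-integer counts (residualized activity) are handled through
    ``gammaln``.
    """
    counts = np.asarray(counts, dtype=float)
    per = int(round(bin_s / grid_s))
    lam_bin = lam_hz[: counts.size * per].reshape(counts.size, per).mean(axis=1)
    mu = lam_bin * bin_s
    return float(np.sum(counts * np.log(mu) - mu - gammaln(counts + 1)))


def _pattern_counts(
    spike_times: np.ndarray, anchors: np.ndarray, L: float, bin_s: float
) -> np.ndarray:
    """Spike counts (trials x bins) in windows [anchor, anchor + L)."""
    st = np.sort(np.asarray(spike_times, float))
    n_bins = int(round(L / bin_s))
    out = np.empty((anchors.size, n_bins), dtype=float)
    for i, a in enumerate(anchors):
        edges = a + bin_s * np.arange(n_bins + 1)
        out[i] = np.histogram(st, bins=edges)[0]
    return out


@dataclass
class RateModel:
    """Per-class KDE rate models for one cell and one training fold."""

    grid: dict
    lam: dict  # class -> rate on grid (Hz)
    windows: dict  # class -> (start, end) relative to reward

    @classmethod
    def fit(
        cls,
        spike_times: np.ndarray,
        reward_times: np.ndarray,
        baseline_window: tuple[float, float],
        expectation_window: tuple[float, float],
        bandwidth_s: float = 0.2,
        grid_s: float = 0.05,
        floor_hz: float = 0.1,
    ) -> "RateModel":
        st = np.sort(np.asarray(spike_times, float))
        windows = {"baseline": baseline_window, "expectation": expectation_window}
        grid, lam = {}, {}
        for c, (a, b) in windows.items():
            rel = np.concatenate(
                [st[np.searchsorted(st, r + a): np.searchsorted(st, r + b)] - r
                 for r in reward_times]
            ) if reward_times.size else np.array([])
            grid[c], lam[c] = kde_rate(
                rel, reward_times.size, (a, b), bandwidth_s, grid_s, floor_hz
            )
        return cls(grid=grid, lam=lam, windows=windows)


@dataclass
class DecodeResult:
    accuracy: dict  # L -> accuracy
    null_quantile: dict  # L -> 99th percentile of shuffled accuracy
    significant: dict  # L -> bool
    min_significant_L: float | None
    n_trials: int
    flags: list = field(default_factory=list)


def _decode_patterns(
    models: list[RateModel],
    patterns: dict,
    grid_s: float,
    bin_s: float,
) -> np.ndarray:
    """Predicted class index (0 baseline, 1 expectation) per test pattern.

    ``patterns[c]`` is a list over cells of (n_patterns x bins) counts drawn
    from class ``c`` windows; log-likelihoods are summed over cells.
    """
    preds = {}
    for true_c, per_cell in patterns.items():
        n_pat = per_cell[0].shape[0]
        ll = np.zeros((n_pat, 2))
        for m, counts in zip(models, per_cell):
            for j, c in enumerate(CLASSES):
                for i in range(n_pat):
                    ll[i, j] += loglik(counts[i], m.lam[c], grid_s, bin_s)
        preds[true_c] = np.argmax(ll, axis=1)
    return preds


def _even_odd_folds(n: int):
    idx = np.arange(n)
    return [(idx % 2 == 0), (idx % 2 == 1)]


def decode(
    cells: list[np.ndarray],
    reward_times: np.ndarray,
    lengths_s,
    baseline_period: tuple[float, float] = (-4.25, -1.5),
    expectation_window: tuple[float, float] = (-1.5, 1.5),
    bandwidth_s: float = 0.2,
    grid_s: float = 0.05,
    bin_s: float = 0.25,
    floor_hz: float = 0.1,
    n_shuffles: int = 500,
    shuffle_quantile: float = 0.99,
    seed: int = 0,
) -> DecodeResult:
    """Baseline-versus-expectation ML decoding for a cell group.

    For each decoding-window length L, each held-out trial contributes two
    test patterns, one per class, anchored at the class-period start; the
    pattern's class is the argmax of summed Poisson log-likelihoods under
    the two fitted rate models.  Accuracy is the fraction correct over all
    test patterns, averaged over the two even/odd folds, with a
    shuffled-label null at the 99th percentile.
    """
    reward_times = np.asarray(reward_times, float)
    n_trials = reward_times.size
    if n_trials < 6:
        raise ValueError("need >= 6 trials to decode")
    rng = child_rng(seed, "decode_shuffle")
    lengths_s = np.atleast_1d(np.asarray(lengths_s, float))
    max_L = {
        "baseline": baseline_period[1] - baseline_period[0],
        "expectation": expectation_window[1] - expectation_window[0],
    }
    anchors = {"baseline": baseline_period[0], "expectation": expectation_window[0]}

    folds = _even_odd_folds(n_trials)
    accuracy, null_q, significant = {}, {}, {}
    flags: list = []
    for L in lengths_s:
        if L > min(max_L.values()) + 1e-9:
            flags.append(f"skipped_L_{L}")
            continue
        correct_flags = []
        for te in folds:
            tr = ~te
            models = [
                RateModel.fit(
                    st, reward_times[tr], baseline_period, expectation_window,
                    bandwidth_s, grid_s, floor_hz,
                )
                for st in cells
            ]
            patterns = {
                c: [
                    _pattern_counts(st, reward_times[te] + anchors[c], L, bin_s)
                    for st in cells
                ]
                for c in CLASSES
            }
            preds = _decode_patterns(models, patterns, grid_s, bin_s)
            for j, c in enumerate(CLASSES):
                correct_flags.append(preds[c] == j)
        correct = np.concatenate(correct_flags)
        acc = float(correct.mean())
        # shuffle-label null: predictions fixed, class labels of the held-out
        # patterns permuted
        labels = np.concatenate(
            [np.full(f.size, j % 2) for j, f in enumerate(correct_flags)]
        )
        pred_cls = np.where(correct, labels, 1 - labels)
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            null[s] = float(np.mean(pred_cls == rng.permutation(labels)))
        q = float(np.quantile(null, shuffle_quantile))
        accuracy[float(L)] = acc
        null_q[float(L)] = q
        significant[float(L)] = bool(acc > q)
    sig_L = [L for L, s in significant.items() if s]
    return DecodeResult(
        accuracy=accuracy,
        null_quantile=null_q,
        significant=significant,
        min_significant_L=min(sig_L) if sig_L else None,
        n_trials=n_trials,
        flags=flags,
    )


def decode_single(cell: np.ndarray, reward_times: np.ndarray, lengths_s,
                  **kwargs) -> DecodeResult:
    """Single-cell decoding; see :func:`decode`."""
    return decode([cell], reward_times, lengths_s, **kwargs)


def decode_population(
    cells: list[np.ndarray],
    reward_times: np.ndarray,
    L: float,
    subset_sizes=None,
    n_draws: int = 50,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Accuracy versus population size at one decoding-window length.

    For each subset size, accuracy is averaged over ``n_draws`` random cell
    subsets (log-likelihoods summed across the subset).  Subset sizes above
    the population are clipped with a flag.
    """
    if len(cells) < 1:
        raise ValueError("need at least one cell")
    rng = child_rng(seed, "population_subsets")
    if subset_sizes is None:
        subset_sizes = [len(cells)]
    out: dict = {"L": float(L), "accuracy_vs_n": {}, "flags": []}
    for size in subset_sizes:
        if size > len(cells):
            out["flags"].append(f"subset_{size}_clipped_to_{len(cells)}")
            size = len(cells)
        accs = []
        n_possible = len(cells) == size
        draws = 1 if n_possible else n_draws
        for _ in range(draws):
            pick = rng.choice(len(cells), size=size, replace=False)
            res = decode([cells[i] for i in pick], reward_times, [L],
                         seed=seed, **kwargs)
            accs.append(res.accuracy[float(L)])
        out["accuracy_vs_n"][int(size)] = float(np.mean(accs))
    return out


def residualized_decode(
    cells: list[np.ndarray],
    reward_times: np.ndarray,
    predicted_rates: list[np.ndarray | None],
    L: float,
    window_s: tuple[float, float] = (-4.25, 1.5),
    bin_s: float = 0.25,
    bandwidth_s: float = 0.2,
    baseline_period: tuple[float, float] = (-4.25, -1.5),
    expectation_window: tuple[float, float] = (-1.5, 1.5),
    floor_hz: float = 0.1,
    n_shuffles: int = 500,
    shuffle_quantile: float = 0.99,
    seed: int = 0,
) -> DecodeResult:
    """Population decoding on speed/acceleration-residualized activity.

    ``predicted_rates[i]`` is cell i's GLM-predicted speed-plus-acceleration
    rate contribution (Hz), per trial and 0.25 s bin over ``window_s``
    (trials x bins); it is subtracted from the binned counts (floored at 0)
    and the rate models are re-estimated from the residualized training
    activity by Gaussian smoothing.  Cells with no prediction are skipped
    with a flag.
    """
    from scipy.ndimage import gaussian_filter1d

    reward_times = np.asarray(reward_times, float)
    n_trials = reward_times.size
    rng = child_rng(seed, "decode_shuffle")
    a, b = window_s
    n_bins = int(round((b - a) / bin_s))
    edges_rel = a + bin_s * np.arange(n_bins + 1)
    centers = 0.5 * (edges_rel[:-1] + edges_rel[1:])

    resid = []
    flags = []
    for i, st in enumerate(cells):
        counts = _pattern_counts(st, reward_times + a, b - a, bin_s)
        pred = predicted_rates[i]
        if pred is None:
            flags.append(f"cell_{i}_skipped_no_fit")
            continue
        resid.append(np.maximum(counts - np.asarray(pred) * bin_s, 0.0))
    if not resid:
        raise ValueError("no cells with GLM predictions")

    cls_sel = {
        "baseline": (centers >= baseline_period[0]) & (centers < baseline_period[1]),
        "expectation": (centers >= expectation_window[0])
        & (centers < expectation_window[1]),
    }
    anchors = {"baseline": baseline_period[0], "expectation": expectation_window[0]}
    n_L = int(round(L / bin_s))
    sigma_bins = bandwidth_s / bin_s

    folds = _even_odd_folds(n_trials)
    correct_flags = []
    for te in folds:
        tr = ~te
        # rate models: smoothed mean residualized rate (Hz) per class window
        lam = {}
        for c, sel in cls_sel.items():
            mean_rate = np.stack([r[tr].mean(axis=0) for r in resid]) / bin_s
            lam[c] = np.maximum(
                gaussian_filter1d(mean_rate, sigma_bins, axis=1, mode="nearest")[
                    :, sel
                ],
                floor_hz,
            )
        for j_true, c in enumerate(CLASSES):
            i0 = int(round((anchors[c] - a) / bin_s))
            test = [r[te][:, i0 : i0 + n_L] for r in resid]
            n_pat = test[0].shape[0]
            ll = np.zeros((n_pat, 2))
            for i_cell, tc in enumerate(test):
                for j, cj in enumerate(CLASSES):
                    mu = lam[cj][i_cell][:n_L] * bin_s
                    ll[:, j] += (
                        tc * np.log(mu)[None, :] - mu[None, :] - gammaln(tc + 1)
                    ).sum(axis=1)
            correct_flags.append(np.argmax(ll, axis=1) == j_true)
    correct = np.concatenate(correct_flags)
    acc = float(correct.mean())
    labels = np.concatenate(
        [np.full(f.size, j % 2) for j, f in enumerate(correct_flags)]
    )
    pred_cls = np.where(correct, labels, 1 - labels)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = float(np.mean(pred_cls == rng.permutation(labels)))
    q = float(np.quantile(null, shuffle_quantile))
    return DecodeResult(
        accuracy={float(L): acc},
        null_quantile={float(L): q},
        significant={float(L): bool(acc > q)},
        min_significant_L=float(L) if acc > q else None,
        n_trials=n_trials,
        flags=flags,
    )
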