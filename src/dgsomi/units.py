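"""Waveform / spike-statistics features and unit classification.

Putative cell classes follow the classic burstiness-by-spike-width plane:

* principal cells (PC): bursting index > 3 and trough-to-peak > 0.45 ms;
* fast-spiking interneurons (FSI): bursting index < 3 and
  trough-to-peak < 0.45 ms;
* wide-spike interneurons (WI): trough-to-peak > 0.45 ms but bursting
  index < 3.

The bursting index is the mean autocorrelogram count in the 3-5 ms bins
divided by the mean count in the 200-300 ms bins (1 ms bins).  PC-class
units are further split into putative granule cells versus mossy cells by
k-means (k = 2) on waveform second-derivative principal components, resting
dentate-spike amplitude (an externally supplied feature) and spatial
information.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "autocorrelogram",
    "bursting_index",
    "trough_to_peak",
    "classify_unit",
    "spatial_information",
    "waveform_pcs",
    "cluster_gc_mc",
]


def autocorrelogram(
    spike_times: np.ndarray, bin_ms: float = 1.0, max_lag_ms: float = 300.0
):
    """Autocorrelogram counts at positive lags.

    Counts ordered spike pairs with lag in each half-open bin
    ``(k*bin, (k+1)*bin]`` ms up to ``max_lag_ms``; zero-lag self pairs are
    excluded.  Returns ``(lags_ms, counts, ok)`` where ``lags_ms`` are bin
    centers and ``ok`` is False when there are fewer than two spikes.
    """
    st = np.asarray(spike_times, dtype=float)
    n_bins = int(round(max_lag_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    lags = 0.5 * (edges[:-1] + edges[1:])
    if st.size < 2:
        return lags, np.zeros(n_bins, dtype=int), False
    max_lag_s = max_lag_ms * 1e-3
    # windowed pair differences: for each spike, partner spikes within
    # max_lag ahead of it, expanded to a flat pair list without a Python
    # per-spike loop
    hi = np.searchsorted(st, st + max_lag_s, side="right")
    lo = np.arange(st.size) + 1
    d_ms = _window_pair_diffs(st, st, lo, hi) * 1e3
    # (0, max_lag] in half-open (k*bin, (k+1)*bin] bins
    idx = np.ceil(d_ms / bin_ms).astype(int) - 1
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return lags, counts, True


def _window_pair_diffs(a: np.ndarray, b: np.ndarray, lo: np.ndarray,
                       hi: np.ndarray) -> np.ndarray:
    """Flat array of b[j] - a[i] for all i and j in [lo[i], hi[i])."""
    counts = np.maximum(hi - lo, 0)
    total = int(counts.sum())
    if total == 0:
        return np.array([], dtype=float)
    starts = np.repeat(lo, counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return b[starts + offsets] - np.repeat(a, counts)


def bursting_index(
    lags_ms: np.ndarray,
    counts: np.ndarray,
    short_ms: tuple[float, float] = (3.0, 5.0),
    long_ms: tuple[float, float] = (200.0, 300.0),
):
    """Short-lag over long-lag mean autocorrelogram count ratio.

    Returns ``(value, ok)``; ``ok`` is False (value 0) when the long-lag
    denominator is empty.
    """
    lags_ms = np.asarray(lags_ms, float)
    counts = np.asarray(counts, float)
    if lags_ms.size and lags_ms[-1] + 0.5 * (lags_ms[1] - lags_ms[0]) < long_ms[1]:
        raise ValueError("autocorrelogram must cover the long-lag window")
    s = counts[(lags_ms > short_ms[0]) & (lags_ms < short_ms[1])]
    l = counts[(lags_ms > long_ms[0]) & (lags_ms < long_ms[1])]
    denom = l.mean() if l.size else 0.0
    if denom == 0:
        return 0.0, False
    return float(s.mean() / denom), True


def trough_to_peak(waveform: np.ndarray, fs_hz: float) -> float:
    """Trough-to-peak duration (ms) of a mean waveform.

    Multi-site waveforms use the site with the largest peak-to-peak
    amplitude.  The duration runs from the global trough to the subsequent
    maximum; a waveform whose minimum is its last sample has no trough.
    """
    wf = np.atleast_2d(np.asarray(waveform, dtype=float))
    site = int(np.argmax(wf.max(axis=1) - wf.min(axis=1)))
    w = wf[site]
    i_trough = int(np.argmin(w))
    if i_trough >= w.size - 1:
        raise ValueError("no trough: waveform minimum at the last sample")
    i_peak = i_trough + int(np.argmax(w[i_trough:]))
    if i_peak == i_trough:
        raise ValueError("no post-trough peak")
    return (i_peak - i_trough) / fs_hz * 1e3


def classify_unit(
    bursting: float,
    trough_to_peak_ms: float,
    bursting_ok: bool = True,
    bi_threshold: float = 3.0,
    ttp_threshold_ms: float = 0.45,
) -> str:
    """PC / FSI / WI from the (bursting index, trough-to-peak) plane.

    Strict inequalities on both thresholds; values exactly on a threshold,
    the bursty-narrow quadrant, and units with an undefined bursting index
    are "unclassified".
    """
    if not bursting_ok or not (np.isfinite(bursting) and np.isfinite(trough_to_peak_ms)):
        return "unclassified"
    if bursting > bi_threshold and trough_to_peak_ms > ttp_threshold_ms:
        return "PC"
    if bursting < bi_threshold and trough_to_peak_ms < ttp_threshold_ms:
        return "FSI"
    if bursting < bi_threshold and trough_to_peak_ms > ttp_threshold_ms:
        return "WI"
    return "unclassified"


def spatial_information(rate_map: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs spatial information in bits/spike.

    ``sum_i p_i (lambda_i / lambda_bar) log2(lambda_i / lambda_bar)`` with
    occupancy probabilities ``p_i`` (normalized to sum 1) and mean rate
    ``lambda_bar = sum_i p_i lambda_i``; zero-rate bins contribute 0.
    Returns NaN when the mean rate is zero.
    """
    lam = np.asarray(rate_map, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    if lam.shape != occ.shape:
        raise ValueError("rate map and occupancy must have the same shape")
    p = occ / occ.sum()
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return float("nan")
    ratio = lam / lam_bar
    terms = np.where(lam > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def waveform_pcs(waveforms: list[np.ndarray], fs_hz: float, window_ms: float = 0.8):
    """First two principal-component scores of the second derivative of each
    unit's dominant-site waveform, 0 to ``window_ms`` ms from the trough.

    The PCA is fit across all units of the session.  Returns an (n_units, 2)
    array.
    """
    n_keep = int(round(window_ms * 1e-3 * fs_hz))
    segs = []
    for wf in waveforms:
        wf = np.atleast_2d(np.asarray(wf, float))
        site = int(np.argmax(wf.max(axis=1) - wf.min(axis=1)))
        w = wf[site]
        i0 = int(np.argmin(w))
        seg = w[i0 : i0 + n_keep]
        if seg.size < n_keep:  # pad by edge value when the window runs out
            seg = np.pad(seg, (0, n_keep - seg.size), mode="edge")
        d2 = np.gradient(np.gradient(seg))
        segs.append(d2)
    X = np.asarray(segs)
    n_comp = min(2, X.shape[0], X.shape[1])
    scores = PCA(n_components=n_comp).fit_transform(X)
    if scores.shape[1] < 2:
        scores = np.pad(scores, ((0, 0), (0, 2 - scores.shape[1])))
    return scores


def cluster_gc_mc(
    features: np.ndarray,
    spatial_info: np.ndarray,
    mean_rates: np.ndarray,
    n_restarts: int = 50,
    seed: int = 0,
):
    """Split PC-class units into putative granule cells vs mossy cells.

    k-means (k = 2, ``n_restarts`` initializations, fixed seed) on z-scored
    features (waveform PCs, dentate-spike amplitude, spatial information).
    The cluster with higher mean spatial information and lower mean firing
    rate is labeled ``putative_GC``.  Returns ``(labels, flags)``.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need >= 4 units to cluster")
    sd = X.std(axis=0)
    flags = []
    if np.any(sd == 0):
        flags.append("constant_feature")
    Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(Xz)
    lab = km.labels_
    if len(set(lab)) < 2:
        flags.append("single_cluster")
        return np.array(["putative_GC"] * X.shape[0]), flags

    si = np.asarray(spatial_info, float)
    rates = np.asarray(mean_rates, float)
    # score each cluster: higher SI and lower rate => granule-cell-like
    score = []
    for c in (0, 1):
        score.append(np.nanmean(si[lab == c]) - np.nanmean(rates[lab == c]))
    gc_cluster = int(np.argmax(score))
    names = np.where(lab == gc_cluster, "putative_GC", "putative_MC")
    return names, flags


def rate_map(
    spike_times: np.ndarray,
    behavior,
    track_length_cm: float = 400.0,
    n_bins: int = 40,
    t_max: float | None = None,
):
    """Occupancy-normalized firing-rate map over track position.

    Returns ``(rates_hz, occupancy_s)`` over ``n_bins`` position bins,
    using behavior samples (and spikes) up to ``t_max``.
    """
    t = behavior["t"].to_numpy()
    pos = behavior["position"].to_numpy()
    dt = float(np.median(np.diff(t)))
    if t_max is not None:
        keep = t < t_max
        t, pos = t[keep], pos[keep]
        spike_times = spike_times[spike_times < t_max]
    edges = np.linspace(0, track_length_cm, n_bins + 1)
    occ = np.histogram(pos, bins=edges)[0] * dt
    spk_pos = np.interp(spike_times, t, pos)
    spk = np.histogram(spk_pos, bins=edges)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occ > 0, spk / np.where(occ > 0, occ, 1.0), 0.0)
    return rates, occ
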