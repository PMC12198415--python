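"""Event-aligned activity and response characterization.

Spike trains are aligned to behavioral events (reward delivery, locomotion
transitions, sensory stimuli) in 100 ms bins over [-5, +5] s, optionally
smoothed with a Gaussian along the time axis (sigma = 1 bin, never across
trials) and z-scored per cell over the full trial x bin matrix.  On top of
the aligned matrices sit the reward-modulation tests (zone versus baseline,
paired Wilcoxon per trial), the delay to maximal activity change, the
ON / OFF / NON locomotion classification, firing-rate-versus-speed
regression, sensory-response tests and the lap-by-lap activity correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .behavior import _paired_wilcoxon

__all__ = [
    "AlignedActivity",
    "align",
    "reward_modulation",
    "delay_to_max_change",
    "onoff_classify",
    "speed_regression",
    "sensory_response",
    "lap_activity_correlation",
]


@dataclass
class AlignedActivity:
    """Event-aligned spike counts: trial x time-bin matrix.

    ``counts`` holds raw counts per half-open bin; ``rate()`` converts to Hz.
    Smoothing and z-scoring return new instances and record their state.
    """

    counts: np.ndarray
    bin_edges_s: np.ndarray  # relative to event onset
    event_times: np.ndarray
    smoothed: bool = False
    zscored: bool = False
    flags: list = field(default_factory=list)

    @property
    def bin_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    def rate(self) -> np.ndarray:
        return self.counts / self.bin_s

    def smooth(self, sigma_bins: float = 1.0) -> "AlignedActivity":
        """Gaussian smoothing along time only (never across trials)."""
        sm = gaussian_filter1d(self.counts.astype(float), sigma_bins, axis=1,
                               mode="nearest")
        return AlignedActivity(sm, self.bin_edges_s, self.event_times,
                               smoothed=True, zscored=self.zscored,
                               flags=list(self.flags))

    def zscore(self) -> "AlignedActivity":
        """z-score over the full matrix (all bins, all trials)."""
        x = self.counts.astype(float)
        sd = x.std()
        if sd == 0:
            raise ValueError("cannot z-score a constant activity matrix")
        return AlignedActivity((x - x.mean()) / sd, self.bin_edges_s,
                               self.event_times, smoothed=self.smoothed,
                               zscored=True, flags=list(self.flags))


def align(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    window_s: tuple[float, float] = (-5.0, 5.0),
    bin_s: float = 0.1,
    recording_end_s: float | None = None,
) -> AlignedActivity:
    """Bin spikes around each event into half-open bins of ``bin_s``.

    Events whose window would exceed the recording (before 0 or after
    ``recording_end_s``) are dropped and flagged.
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    ev = np.asarray(event_times, dtype=float)
    if ev.size == 0:
        raise ValueError("no events to align to")
    flags = []
    keep = ev + window_s[0] >= 0
    if recording_end_s is not None:
        keep &= ev + window_s[1] <= recording_end_s
    if not np.all(keep):
        flags.append(f"dropped_{int((~keep).sum())}_edge_events")
    ev = ev[keep]
    if ev.size == 0:
        raise ValueError("all events fall outside the recording")

    n_bins = int(round((window_s[1] - window_s[0]) / bin_s))
    edges = window_s[0] + bin_s * np.arange(n_bins + 1)
    counts = np.empty((ev.size, n_bins), dtype=int)
    for k, e in enumerate(ev):
        counts[k] = np.histogram(st, bins=e + edges)[0]
    return AlignedActivity(counts, edges, ev, flags=flags)


# --------------------------------------------------------------------------- #
# reward modulation
# --------------------------------------------------------------------------- #

def _window_rates(
    spike_times: np.ndarray, event_times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    st = np.sort(np.asarray(spike_times, float))
    a, b = window
    n = np.searchsorted(st, event_times + b) - np.searchsorted(st, event_times + a)
    return n / (b - a)


def reward_modulation(
    spike_times: np.ndarray,
    reward_times: np.ndarray,
    baseline_window_s: tuple[float, float] = (-6.0, -4.0),
    pre_window_s: tuple[float, float] = (-2.0, 0.0),
    post_window_s: tuple[float, float] = (0.0, 2.0),
    alpha: float = 0.05,
    min_trials: int = 10,
) -> dict:
    """Zone-versus-baseline reward-modulation tests.

    Per zone (pre, post), a paired Wilcoxon of per-trial mean rate against
    the per-trial baseline rate, two-sided at ``alpha``; direction from the
    median difference.  A cell is "anticipatory" when its pre-zone is
    up-modulated, "non-anticipatory" when only modulated elsewhere,
    "unmodulated" otherwise.
    """
    reward_times = np.asarray(reward_times, float)
    if reward_times.size < min_trials:
        raise ValueError(
            f"need >= {min_trials} rewarded trials, got {reward_times.size}"
        )
    base = _window_rates(spike_times, reward_times, baseline_window_s)
    out: dict = {"n_trials": int(reward_times.size), "alpha": alpha}
    modulated = []
    for zone, win in (("pre", pre_window_s), ("post", post_window_s)):
        r = _window_rates(spike_times, reward_times, win)
        p = _paired_wilcoxon(r, base, "two-sided")
        med = float(np.median(r - base))
        direction = "none"
        if p < alpha:
            direction = "up" if med > 0 else "down" if med < 0 else (
                "up" if np.mean(r - base) > 0 else "down"
            )
        out[f"{zone}_p"] = p
        out[f"{zone}_direction"] = direction
        if direction != "none":
            modulated.append(zone)
    if out["pre_direction"] == "up":
        out["classification"] = "anticipatory"
    elif modulated:
        out["classification"] = "non-anticipatory"
    else:
        out["classification"] = "unmodulated"
    return out


def delay_to_max_change(
    aligned: AlignedActivity,
    search_window_s: tuple[float, float] = (-2.0, 2.0),
    baseline_window_s: tuple[float, float] = (-6.0, -4.0),
    sigma_bins: float = 1.0,
) -> float:
    """Time from event onset to the maximal absolute z-scored activity
    change relative to baseline.

    Works on the smoothed, z-scored, trial-averaged trace; the baseline
    reference is the mean z over the baseline window clipped to the aligned
    window.  Ties break to the earliest bin.
    """
    z = aligned
    if not z.zscored:
        z = z.zscore()
    if not z.smoothed:
        z = z.smooth(sigma_bins)
    trace = z.counts.mean(axis=0)
    centers = z.bin_centers_s
    lo = max(baseline_window_s[0], z.bin_edges_s[0])
    hi = max(baseline_window_s[1], z.bin_edges_s[0] + z.bin_s)
    base_sel = (centers >= lo) & (centers < hi)
    if not base_sel.any():
        raise ValueError("baseline window outside the aligned window")
    z_base = trace[base_sel].mean()
    sel = (centers >= search_window_s[0]) & (centers <= search_window_s[1])
    diff = np.abs(trace[sel] - z_base)
    if np.ptp(diff) == 0:
        raise ValueError("no modulation: flat trace in the search window")
    return float(centers[sel][int(np.argmax(diff))])


# --------------------------------------------------------------------------- #
# locomotion
# --------------------------------------------------------------------------- #

def onoff_classify(
    spike_times: np.ndarray,
    onset_times: np.ndarray,
    offset_times: np.ndarray,
    immobile_window_s: tuple[float, float] = (-3.0, -1.0),
    moving_window_s: tuple[float, float] = (1.0, 3.0),
    alpha: float = 0.05,
    min_transitions: int = 8,
) -> dict:
    """ON / OFF / NON classification at running transitions.

    OFF: firing drops at running onset and rises at offset (both paired
    Wilcoxon significant); ON: both reversed; NON otherwise (including too
    few transitions, which is flagged).  Around an onset the immobile side
    is before it, the moving side after; at an offset the windows swap roles.
    """
    out: dict = {"flags": []}
    if onset_times.size < min_transitions or offset_times.size < min_transitions:
        out["classification"] = "NON"
        out["flags"].append("too_few_transitions")
        return out
    on_imm = _window_rates(spike_times, onset_times, immobile_window_s)
    on_mov = _window_rates(spike_times, onset_times, moving_window_s)
    off_mov = _window_rates(spike_times, offset_times, immobile_window_s)
    off_imm = _window_rates(spike_times, offset_times, moving_window_s)

    p_on_drop = _paired_wilcoxon(on_mov, on_imm, "less")
    p_off_rise = _paired_wilcoxon(off_imm, off_mov, "greater")
    p_on_rise = _paired_wilcoxon(on_mov, on_imm, "greater")
    p_off_drop = _paired_wilcoxon(off_imm, off_mov, "less")

    if p_on_drop < alpha and p_off_rise < alpha:
        out["classification"] = "OFF"
    elif p_on_rise < alpha and p_off_drop < alpha:
        out["classification"] = "ON"
    else:
        out["classification"] = "NON"
    out.update(
        p_onset_drop=p_on_drop, p_offset_rise=p_off_rise,
        p_onset_rise=p_on_rise, p_offset_drop=p_off_drop,
        n_onsets=int(onset_times.size), n_offsets=int(offset_times.size),
    )
    return out


def speed_regression(
    spike_times: np.ndarray,
    behavior: pd.DataFrame,
    bin_s: float = 0.1,
    steady_state_only: bool = False,
    run_thr_cms: float = 3.0,
    t_max: float | None = None,
    min_bins: int = 100,
) -> dict:
    """Linear least-squares regression of binned firing rate on binned speed.

    100 ms bins by default; ``steady_state_only`` keeps bins whose mean
    speed exceeds the locomotion threshold.  Constant speed leaves the
    slope undefined (r = 0, flagged).
    """
    t = behavior["t"].to_numpy()
    speed = behavior["speed"].to_numpy()
    end = t_max if t_max is not None else t[-1]
    edges = np.arange(t[0], end, bin_s)
    if edges.size < 2:
        raise ValueError("trace too short for speed regression")
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, edges.size - 2)
    sp_sum = np.bincount(idx, weights=speed, minlength=edges.size - 1)
    sp_n = np.bincount(idx, minlength=edges.size - 1)
    sp = sp_sum / np.maximum(sp_n, 1)
    st = np.asarray(spike_times, float)
    st = st[(st >= edges[0]) & (st < edges[-1])]
    rate = np.histogram(st, bins=edges)[0] / bin_s

    keep = sp_n > 0
    if steady_state_only:
        keep &= sp > run_thr_cms
    sp, rate = sp[keep], rate[keep]
    if sp.size < min_bins:
        raise ValueError(f"need >= {min_bins} usable bins, got {sp.size}")
    if np.ptp(sp) == 0:
        return {"slope": 0.0, "r": 0.0, "p": 1.0, "n_bins": int(sp.size),
                "degenerate": True}
    res = stats.linregress(sp, rate)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "n_bins": int(sp.size),
        "degenerate": False,
    }


def sensory_response(
    spike_times: np.ndarray,
    stim_events: pd.DataFrame,
    alpha: float = 0.05,
    min_events: int = 15,
) -> dict:
    """Per-modality during-versus-pre spike-count comparison.

    ``stim_events`` needs columns ``t``, ``kind`` and ``duration``; the
    comparison epoch equals each stimulus duration.  Modalities with fewer
    than ``min_events`` stimuli are skipped with a flag.
    """
    st = np.sort(np.asarray(spike_times, float))
    out: dict = {}
    for kind, grp in stim_events.groupby("kind"):
        onsets = grp["t"].to_numpy(float)
        durs = grp["duration"].to_numpy(float)
        if onsets.size < min_events:
            out[kind] = {"direction": "skipped", "p": np.nan,
                         "flag": "too_few_events"}
            continue
        during = (np.searchsorted(st, onsets + durs) - np.searchsorted(st, onsets)
                  ).astype(float)
        pre = (np.searchsorted(st, onsets) - np.searchsorted(st, onsets - durs)
               ).astype(float)
        p = _paired_wilcoxon(during, pre, "two-sided")
        med = float(np.median(during - pre))
        direction = "none"
        if p < alpha:
            direction = "up" if med > 0 or (med == 0 and np.mean(during - pre) > 0) \
                else "down"
        out[kind] = {"direction": direction, "p": p, "n": int(onsets.size)}
    return out


def lap_activity_correlation(
    aligned: AlignedActivity,
    group_a: np.ndarray,
    group_b: np.ndarray,
    sigma_bins: float = 1.0,
) -> dict:
    """Mean Pearson correlation of smoothed lap activity vectors between two
    lap groups (all A x B pairs); constant vectors are excluded and flagged.
    """
    sm = aligned if aligned.smoothed else aligned.smooth(sigma_bins)
    X = sm.counts
    group_a = np.asarray(group_a, int)
    group_b = np.asarray(group_b, int)
    if group_a.size < 2 or group_b.size < 2:
        raise ValueError("need >= 2 laps per group")
    if X.shape[1] < 10:
        raise ValueError("need >= 10 bins per lap vector")
    rs, n_const = [], 0
    for a in group_a:
        for b in group_b:
            va, vb = X[a], X[b]
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                n_const += 1
                continue
            rs.append(stats.pearsonr(va, vb).statistic)
    flags = ["constant_laps_excluded"] if n_const else []
    if not rs:
        return {"mean_r": float("nan"), "n_pairs": 0, "flags": ["all_constant"]}
    return {"mean_r": float(np.mean(rs)), "n_pairs": len(rs), "flags": flags}
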