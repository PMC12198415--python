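"""Behavioral analysis.

Motion-state segmentation of the running-speed trace, detection of running
on/offsets, per-lap lick and speed statistics in the peri-reward zones,
the expert / non-expert session criterion, the anticipatory-licking
performance score, and the lick-rate-versus-lap regression.

Conventions: immobility is speed < 0.5 cm/s, steady-state locomotion is
speed > 3 cm/s (the band in between is "intermediate"); a running onset is a
minimum of 3 s immobility followed by a transition reaching 3 cm/s within
3 s, the offset the mirror image.  Peri-reward windows are the 2 s pre-zone
[-2, 0) s, the 2 s post-zone [0, 2) s and a baseline window [-6, -4) s
relative to reward onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MotionSegments",
    "segment_motion",
    "zone_rates",
    "classify_performance",
    "performance_score",
    "lick_lap_trend",
]


@dataclass
class MotionSegments:
    """Non-overlapping (start, end, state) intervals covering the trace plus
    detected running transitions (time, kind in {onset, offset})."""

    intervals: pd.DataFrame
    transitions: pd.DataFrame
    dt_s: float


def _state_codes(speed: np.ndarray, immobile_thr: float, run_thr: float):
    state = np.full(speed.size, 1, dtype=int)  # 1 = intermediate
    state[speed < immobile_thr] = 0
    state[speed > run_thr] = 2
    return state


def segment_motion(
    t: np.ndarray,
    speed: np.ndarray,
    immobile_thr_cms: float = 0.5,
    run_thr_cms: float = 3.0,
    min_immobility_s: float = 3.0,
    max_transition_s: float = 3.0,
) -> MotionSegments:
    """Segment a uniformly sampled speed trace into motion states and find
    running on/offsets.

    An onset is reported when an immobility interval of at least
    ``min_immobility_s`` is followed by the speed reaching ``run_thr_cms``
    within ``max_transition_s``; the onset time is the first sample at or
    above ``immobile_thr_cms`` of the qualifying ramp.  Offsets mirror this:
    locomotion declining below ``immobile_thr_cms`` within
    ``max_transition_s`` and staying immobile for at least
    ``min_immobility_s``; the offset time is the first immobile sample.
    """
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if t.size != speed.size:
        raise ValueError("t and speed must have equal length")
    if t.size < 2:
        raise ValueError("need at least two samples")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > 1e-6 + 1e-6 * dt):
        raise ValueError("speed trace must be uniformly sampled")

    state = _state_codes(speed, immobile_thr_cms, run_thr_cms)

    # run-length encode into intervals
    change = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [state.size]])
    names = np.array(["immobile", "intermediate", "locomotion"])
    intervals = pd.DataFrame(
        {
            "start": t[starts],
            "end": np.concatenate([t[change], [t[-1] + dt]]),
            "state": names[state[starts]],
        }
    )

    onsets, offsets = [], []
    imm = intervals[intervals["state"] == "immobile"]
    for _, row in imm.iterrows():
        if row["end"] - row["start"] < min_immobility_s:
            continue
        # onset: after this immobility, does speed reach run_thr within limit?
        i_end = int(round((row["end"] - t[0]) / dt))
        if i_end < state.size:
            horizon = min(i_end + int(round(max_transition_s / dt)) + 1, state.size)
            if np.any(speed[i_end:horizon] >= run_thr_cms):
                onsets.append(t[i_end])  # first sample >= immobile threshold
        # offset: was there locomotion within limit before this immobility?
        i_start = int(round((row["start"] - t[0]) / dt))
        lo = max(i_start - int(round(max_transition_s / dt)) - 1, 0)
        if i_start > 0 and np.any(speed[lo:i_start] >= run_thr_cms):
            offsets.append(t[i_start])

    transitions = pd.concat(
        [
            pd.DataFrame({"t": onsets, "kind": "onset"}),
            pd.DataFrame({"t": offsets, "kind": "offset"}),
        ],
        ignore_index=True,
    ).sort_values("t").reset_index(drop=True)
    return MotionSegments(intervals=intervals, transitions=transitions, dt_s=dt)


def zone_rates(
    lick_times: np.ndarray,
    behavior: pd.DataFrame,
    reward_times: np.ndarray,
    baseline_window_s: tuple[float, float] = (-6.0, -4.0),
    pre_window_s: tuple[float, float] = (-2.0, 0.0),
    post_window_s: tuple[float, float] = (0.0, 2.0),
) -> pd.DataFrame:
    """Per-reward lick rates (Hz) and mean speeds (cm/s) in the baseline,
    pre- and post-reward windows.

    Returns one row per reward with columns ``lick_{baseline,pre,post}`` and
    ``speed_{baseline,pre,post}``; rewards whose baseline window starts
    before the trace are flagged ``clipped``.
    """
    lick_times = np.sort(np.asarray(lick_times, dtype=float))
    reward_times = np.asarray(reward_times, dtype=float)
    t = behavior["t"].to_numpy()
    speed = behavior["speed"].to_numpy()

    rows = []
    for k, r in enumerate(reward_times):
        row = {"reward_index": k, "t_reward": r, "clipped": False}
        for name, (a, b) in (
            ("baseline", baseline_window_s),
            ("pre", pre_window_s),
            ("post", post_window_s),
        ):
            lo, hi = r + a, r + b
            if lo < t[0] or hi > t[-1]:
                row["clipped"] = True
            n = np.searchsorted(lick_times, hi) - np.searchsorted(lick_times, lo)
            row[f"lick_{name}"] = n / (b - a)
            sel = (t >= lo) & (t < hi)
            row[f"speed_{name}"] = float(speed[sel].mean()) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Wilcoxon signed-rank p-value of x vs y; 1.0 when degenerate."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[np.isfinite(d)]
    if d.size < 5 or np.all(d == 0):
        return 1.0
    try:
        return float(stats.wilcoxon(d, alternative=alternative).pvalue)
    except ValueError:
        return 1.0


def classify_performance(
    zr: pd.DataFrame, alpha: float = 0.05, min_laps: int = 10
) -> dict:
    """Expert / non-expert session criterion.

    Expert iff, across rewarded laps, (a) pre-zone lick rate exceeds the
    baseline lick rate (one-sided Wilcoxon signed-rank) and (b) pre-zone
    running speed is below the baseline speed, both at ``alpha``.
    """
    if len(zr) < min_laps:
        raise ValueError(
            f"need >= {min_laps} rewarded laps for the expert criterion, got {len(zr)}"
        )
    p_lick = _paired_wilcoxon(zr["lick_pre"], zr["lick_baseline"], "greater")
    p_speed = _paired_wilcoxon(zr["speed_pre"], zr["speed_baseline"], "less")
    verdict = "expert" if (p_lick < alpha and p_speed < alpha) else "nonexpert"
    return {
        "performance": verdict,
        "p_lick": p_lick,
        "p_speed": p_speed,
        "n_laps": int(len(zr)),
        "alpha": alpha,
    }


def performance_score(zr: pd.DataFrame) -> float:
    """Fraction of laps with anticipatory licking (pre-zone rate above
    baseline rate)."""
    if len(zr) == 0:
        raise ValueError("need at least one rewarded lap")
    return float(np.mean(zr["lick_pre"].to_numpy() > zr["lick_baseline"].to_numpy()))


def lick_lap_trend(per_lap_rates: np.ndarray) -> dict:
    """Least-squares regression of lick rate on lap number with Pearson r.

    Returns slope (Hz per lap), intercept, Pearson r and its two-sided p.
    Constant rates leave r undefined; reported as r = 0 with ``degenerate``.
    """
    y = np.asarray(per_lap_rates, dtype=float)
    if y.size < 5:
        raise ValueError("need >= 5 laps for the lap trend")
    x = np.arange(y.size, dtype=float)
    if np.ptp(y) == 0:
        return {
            "slope": 0.0,
            "intercept": float(y[0]),
            "r": 0.0,
            "p": 1.0,
            "degenerate": True,
        }
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "degenerate": False,
    }
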