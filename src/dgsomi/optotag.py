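"""Optogenetic tagging.

Classifies units by their response to light pulses at the dentate-gyrus
fiber: directly driven SOM interneurons (SOMI: significant rate increase
with first light-triggered spikes within 5 ms of pulse onset), disinhibited
units (significant increase, first spikes later than 5 ms), inhibited units
(significant decrease), or no response.  SOMIs are subtyped as projecting
versus local by whether stimulating their axons in the fimbria also drives
them.

The "first light-triggered spike within 5 ms" rule is operationalized as
the median over pulses of the first-spike latency, which is robust to
occasional spontaneous spikes just after pulse onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import _paired_wilcoxon

__all__ = ["LightResponse", "light_response", "tag_unit", "subtype_projection"]


@dataclass
class LightResponse:
    """Per-unit response to one pulse set (one site, one duration)."""

    count_during: np.ndarray
    count_pre: np.ndarray
    first_spike_latency_ms: np.ndarray  # NaN where no spike during the pulse
    p_value: float
    direction: str  # increase | decrease | none
    median_first_latency_ms: float
    n_pulses: int
    flags: list


def light_response(
    spike_times: np.ndarray,
    pulse_onsets: np.ndarray,
    pulse_duration_s: float,
    alpha: float = 0.05,
    min_pulses: int = 20,
    late_increase_check: bool = False,
) -> LightResponse:
    """Compare spike counts during pulses against the same-length
    pre-stimulation epochs (paired Wilcoxon signed-rank).

    Direction is read from the median count difference when the test is
    significant at ``alpha``.  The first-spike latency per pulse is the time
    from pulse onset to the first spike inside the pulse (NaN if none).
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    onsets = np.asarray(pulse_onsets, dtype=float)
    if onsets.size < min_pulses:
        raise ValueError(
            f"need >= {min_pulses} pulses for the light-response test, got {onsets.size}"
        )
    flags: list = []
    i_on = np.searchsorted(st, onsets)
    i_off = np.searchsorted(st, onsets + pulse_duration_s)
    i_pre = np.searchsorted(st, onsets - pulse_duration_s)
    during = (i_off - i_on).astype(float)
    pre = (i_on - i_pre).astype(float)

    latency = np.full(onsets.size, np.nan)
    has = i_off > i_on
    latency[has] = (st[i_on[has]] - onsets[has]) * 1e3

    p = _paired_wilcoxon(during, pre, "two-sided")
    med_diff = float(np.median(during - pre))
    if p < alpha and med_diff != 0:
        direction = "increase" if med_diff > 0 else "decrease"
    elif p < alpha:
        direction = "increase" if np.mean(during - pre) > 0 else "decrease"
    else:
        direction = "none"
    med_lat = float(np.nanmedian(latency)) if np.any(has) else float("nan")
    if not np.any(has):
        flags.append("silent_during_pulses")

    resp = LightResponse(
        count_during=during,
        count_pre=pre,
        first_spike_latency_ms=latency,
        p_value=p,
        direction=direction,
        median_first_latency_ms=med_lat,
        n_pulses=int(onsets.size),
        flags=flags,
    )
    if late_increase_check and direction == "increase":
        # auxiliary flag: early increase followed by suppression later in the
        # pulse marks a SOMI inhibited by other SOMIs
        early = np.searchsorted(st, onsets + 5e-3) - i_on
        late = i_off - np.searchsorted(st, onsets + 5e-3)
        late_base = (
            np.searchsorted(st, onsets - 5e-3 + pulse_duration_s) - i_pre
        )
        p_late = _paired_wilcoxon(late.astype(float), late_base.astype(float),
                                  "less")
        if np.median(early) > 0 and p_late < alpha:
            resp.flags.append("early_increase_late_decrease")
    return resp


def tag_unit(resp_dg: LightResponse, latency_threshold_ms: float = 5.0) -> str:
    """SOMI / SOM_disinh / SOM_inh / NONE from the dentate-site response.

    SOMI: significant increase with median first-spike latency at or below
    the threshold; disinhibited: significant increase but later first
    spikes; inhibited: significant decrease.
    """
    if resp_dg.direction == "increase":
        if (
            np.isfinite(resp_dg.median_first_latency_ms)
            and resp_dg.median_first_latency_ms <= latency_threshold_ms
        ):
            return "SOMI"
        return "SOM_disinh"
    if resp_dg.direction == "decrease":
        return "SOM_inh"
    return "NONE"


def subtype_projection(tag_dg: str, resp_fimbria: LightResponse | None) -> str:
    """Projection subtype of a tagged SOMI from fimbria (axonal) stimulation:
    ``proj`` when fimbria pulses significantly increase firing, ``local``
    otherwise; ``NA`` for non-SOMIs or when no fimbria protocol exists."""
    if tag_dg != "SOMI" or resp_fimbria is None:
        return "NA"
    return "proj" if resp_fimbria.direction == "increase" else "local"
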