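"""Session data model.

A :class:`Session` bundles everything one recording contributes to the
pipeline: sorted single units with mean waveforms, continuous behavior traces
(track position and running speed), an event table (rewards, licks, light
pulses, sensory stimuli) and a lap table, plus the geometric metadata of the
400 cm circular track.

All timestamps are seconds (float64) on one common clock; time bins throughout
the pipeline are half-open ``[t, t + dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Unit", "Session", "EVENT_KINDS", "SessionError"]

EVENT_KINDS = (
    "reward",
    "lick",
    "light_dg",
    "light_fimbria",
    "stim_visual",
    "stim_sound",
    "stim_airpuff",
    "random_reward",
)


class SessionError(ValueError):
    """Raised when a session bundle violates a structural invariant."""


@dataclass
class Unit:
    """One sorted unit: spike times, mean waveform, derived features, labels.

    ``waveform`` is a (site, sample) matrix of the spike-triggered average on
    each recording site; feature extraction uses the site with the largest
    peak-to-peak amplitude.  ``features`` and ``labels`` start empty and are
    filled by the classification stages.
    """

    unit_id: int
    spike_times: np.ndarray
    waveform: np.ndarray
    waveform_fs_hz: float = 30_000.0
    features: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=float))
        if self.spike_times.ndim != 1:
            raise SessionError(f"unit {self.unit_id}: spike_times must be 1-D")
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise SessionError(
                f"unit {self.unit_id}: spike_times not strictly increasing"
            )
        if self.spike_times.size and (
            not np.all(np.isfinite(self.spike_times)) or self.spike_times[0] < 0
        ):
            raise SessionError(
                f"unit {self.unit_id}: spike times must be finite, non-negative"
            )
        if self.waveform.shape[0] < 1 or self.waveform.shape[1] < 3:
            raise SessionError(f"unit {self.unit_id}: waveform too small")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def mean_rate(self, duration_s: float) -> float:
        return self.n_spikes / duration_s if duration_s > 0 else np.nan


@dataclass
class Session:
    """Container for one recording session.

    Parameters
    ----------
    units
        List of :class:`Unit`.
    behavior
        DataFrame with columns ``t`` (s, uniformly sampled), ``position``
        (cm, in ``[0, track_length_cm)``) and ``speed`` (cm/s).
    events
        DataFrame with columns ``t`` (s), ``kind`` (one of
        :data:`EVENT_KINDS`) and ``duration`` (s; 0 for point events).
    laps
        DataFrame with columns ``lap`` (0-based index), ``start`` and
        ``end`` (s).
    meta
        Track geometry and window conventions; see
        :class:`~dgsomi.config.PipelineConfig` for defaults.
    """

    units: list[Unit]
    behavior: pd.DataFrame
    events: pd.DataFrame
    laps: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meta.setdefault("track_length_cm", 400.0)
        self.meta.setdefault("pre_zone_s", 2.0)
        self.meta.setdefault("post_zone_s", 2.0)
        self.meta.setdefault("baseline_window_s", (-6.0, -4.0))
        self.validate()

    # ------------------------------------------------------------------ access
    def event_times(self, kind: str) -> np.ndarray:
        if kind not in EVENT_KINDS:
            raise SessionError(f"unknown event kind {kind!r}")
        sel = self.events[self.events["kind"] == kind]
        return sel["t"].to_numpy(dtype=float)

    def event_rows(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind].reset_index(drop=True)

    @property
    def reward_times(self) -> np.ndarray:
        return self.event_times("reward")

    @property
    def duration_s(self) -> float:
        t = self.behavior["t"].to_numpy()
        ends = [t[-1]] if t.size else [0.0]
        if len(self.events):
            ends.append(float(self.events["t"].max()))
        for u in self.units:
            if u.n_spikes:
                ends.append(float(u.spike_times[-1]))
        return float(max(ends))

    def unit_by_id(self, unit_id: int) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    # --------------------------------------------------------------- validation
    def validate(self) -> None:
        for col in ("t", "position", "speed"):
            if col not in self.behavior.columns:
                raise SessionError(f"behavior trace missing column {col!r}")
        t = self.behavior["t"].to_numpy(dtype=float)
        if t.size and (np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0) or t[0] < 0):
            raise SessionError("behavior time base must be finite, increasing, >= 0")
        pos = self.behavior["position"].to_numpy(dtype=float)
        L = float(self.meta["track_length_cm"])
        if pos.size and (pos.min() < 0 or pos.max() >= L):
            raise SessionError(f"position outside [0, {L}) cm")

        for col in ("t", "kind", "duration"):
            if col not in self.events.columns:
                raise SessionError(f"event table missing column {col!r}")
        bad = set(self.events["kind"]) - set(EVENT_KINDS)
        if bad:
            raise SessionError(f"unknown event kinds: {sorted(bad)}")
        for kind, grp in self.events.groupby("kind"):
            et = grp["t"].to_numpy(dtype=float)
            if np.any(~np.isfinite(et)) or np.any(et < 0):
                raise SessionError(f"{kind} events must have finite, >= 0 times")
            if np.any(np.diff(et) < 0):
                raise SessionError(f"{kind} events not sorted by time")

        for col in ("lap", "start", "end"):
            if col not in self.laps.columns:
                raise SessionError(f"lap table missing column {col!r}")
        starts = self.laps["start"].to_numpy(dtype=float)
        ends = self.laps["end"].to_numpy(dtype=float)
        if np.any(ends <= starts):
            raise SessionError("lap end must exceed lap start")
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            raise SessionError("laps overlap")

        # every reward lies inside exactly one lap interval
        for rt in self.event_times("reward"):
            inside = np.sum((starts <= rt) & (rt < ends))
            if inside != 1:
                raise SessionError(
                    f"reward event at t={rt:.3f} s lies in {inside} laps (expected 1)"
                )
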