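"""Synthetic session generator.

Emulates a head-fixed mouse running laps on a 4 m circular virtual track with
two fixed reward sites, together with extracellularly recorded units whose
statistics carry every structure the downstream analyses look for:

* expert behavior — anticipatory licking and deceleration in the 2 s
  pre-reward zone — versus non-expert behavior (licking only after reward,
  no deceleration);
* immobility bouts (>= 3 s) followed by running, so locomotion on/offset
  detection has transitions to find;
* units of three waveform/burstiness classes (bursty wide-spike principal
  cells, fast-spiking narrow interneurons, non-bursty wide-spike
  interneurons), with parametric biphasic waveforms;
* reward modulation with predictive (pre-reward peak), consumption
  (post-reward peak), suppressed or boxcar ("step") profiles;
* locomotion-state modulation (ON / OFF / NON) and linear speed tuning;
* ChR2-style light responses at a dentate-gyrus fiber and an axonal
  (fimbria) fiber, with deterministic first-spike latencies, plus
  light-inhibited and light-disinhibited units;
* monosynaptic coupling injected as probabilistic spike transmission at
  1-4 ms latency.

Spike trains are inhomogeneous Poisson (thinning), matching the Poisson
assumptions of the decoder and of the cross-correlogram null.  Everything is
driven by one seed; the generator returns a ground-truth manifest sufficient
to score every downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .rng import child_rng
from .session import Session, Unit

__all__ = [
    "RewardModulation",
    "OptoSpec",
    "UnitSpec",
    "SynapseSpec",
    "SynthConfig",
    "generate_behavior",
    "generate_spike_train",
    "inject_synapse",
    "apply_light_protocol",
    "generate_session",
    "default_expert_config",
    "default_nonexpert_config",
    "make_waveform",
]


# --------------------------------------------------------------------------- #
# specs
# --------------------------------------------------------------------------- #

@dataclass
class RewardModulation:
    """Multiplicative peri-reward rate modulation.

    ``profile`` names the ground-truth category; ``shape`` selects a Gaussian
    bump (center ``peak_time_s``, SD ``width_s``) or a boxcar over
    ``window_s``, both relative to reward onset.  ``peak_gain`` is the factor
    at the peak (1 = no modulation; < 1 = suppression).
    """

    profile: str = "none"  # predictive | consumption | suppressed | none
    shape: str = "gaussian"  # gaussian | step
    peak_gain: float = 1.0
    peak_time_s: float = -0.3
    width_s: float = 0.5
    window_s: tuple[float, float] = (-1.5, 0.0)


@dataclass
class OptoSpec:
    is_chr2: bool = False
    latency_ms: float = 2.0
    is_inhibited: bool = False
    is_disinhibited: bool = False
    projects_to_fimbria: bool = False
    gain: float = 10.0  # rate factor during pulses for ChR2 / disinhibited
    disinh_delay_ms: float = 8.0


@dataclass
class UnitSpec:
    unit_class: str = "WI"  # PC | FSI | WI
    baseline_rate_hz: float = 5.0
    reward_modulation: RewardModulation = field(default_factory=RewardModulation)
    locomotion_modulation: str = "NON"  # ON | OFF | NON
    speed_slope: float = 0.0  # additive Hz per cm/s
    opto: OptoSpec = field(default_factory=OptoSpec)
    burst_prob: float = 0.0  # doublet (4 ms) probability per spike
    trough_to_peak_ms: float = 0.6
    place_field: Optional[tuple[float, float, float]] = None  # center cm, sd cm, gain
    ds_amplitude: float = 0.0
    sensory_gain: dict = field(default_factory=dict)  # kind -> rate factor
    gc_mc: str = "NA"  # putative_GC | putative_MC | NA
    #: 0..1 — how strongly the per-trial reward-modulation amplitude follows
    #: the lap's licking intensity (shared lap-to-lap variability)
    lick_coupling: float = 0.0
    #: additive rate coupling to the instantaneous lick rate (Hz per lick/s)
    lick_rate_gain: float = 0.0


@dataclass
class SynapseSpec:
    pre_id: int
    post_id: int
    efficacy: float = 0.3
    latency_ms: float = 2.0
    jitter_ms: float = 0.2


@dataclass
class SynthConfig:
    n_laps: int = 30
    reward_positions_cm: tuple[float, float] = (100.0, 300.0)
    track_length_cm: float = 400.0
    performance: str = "expert"  # expert | nonexpert
    cruise_speed_cms: float = 20.0
    reward_approach_speed_cms: float = 5.0  # expert speed at reward onset
    pause_every_lap: bool = True
    lick_rate_baseline_hz: float = 0.5
    lick_rate_pre_hz: float = 4.0  # expert only
    lick_rate_post_hz: float = 6.0
    #: SD of the log-normal lap-to-lap licking-intensity factor
    lick_amp_sigma: float = 0.4
    behavior_dt_s: float = 0.01
    rate_dt_s: float = 0.005
    # light protocol
    n_pulses_dg: int = 100
    n_pulses_fimbria: int = 100
    pulse_duration_s: float = 0.25
    pulse_isi_s: float = 5.0
    # sensory protocol (0 disables)
    sensory_n_stimuli: int = 0
    sensory_duration_s: float = 0.5
    sensory_isi_s: float = 3.0
    units: list[UnitSpec] = field(default_factory=list)
    synapses: list[SynapseSpec] = field(default_factory=list)
    seed: int = 0


# --------------------------------------------------------------------------- #
# behavior
# --------------------------------------------------------------------------- #

def _segments_for_session(cfg: SynthConfig, rng: np.random.Generator):
    """Piecewise-linear speed segments (duration_s, v0, v1) for the whole
    behavioral period, plus the cumulative distance at each reward delivery.

    The session is built leg by leg, a leg running from one reward site to
    the next (first leg: track start to the first site).  Expert legs end
    with a 2 s linear deceleration to the approach speed; after the reward
    the animal creeps for 1 s, then re-accelerates.  One leg per lap contains
    an immobility bout (deceleration to rest, >= 3.5 s at rest, ramp back),
    placed just after the post-reward segment so the pre-reward baseline
    window of the next site stays in steady-state running.
    """
    v = cfg.cruise_speed_cms
    v_app = cfg.reward_approach_speed_cms
    expert = cfg.performance == "expert"
    r1, r2 = cfg.reward_positions_cm
    L = cfg.track_length_cm

    segs: list[tuple[float, float, float]] = []
    reward_dist: list[float] = []

    def add(dur, v0, v1):
        if dur > 0:
            segs.append((float(dur), float(v0), float(v1)))

    def dist(dur, v0, v1):
        return 0.5 * (v0 + v1) * dur

    # initial immobility bout then ramp up (gives a first running onset)
    add(4.0, 0.0, 0.0)
    add(1.5, 0.0, v)
    covered = dist(1.5, 0.0, v)

    # absolute distances of successive reward deliveries
    targets = []
    for lap in range(cfg.n_laps):
        targets.append(lap * L + r1)
        targets.append(lap * L + r2)

    pos = covered
    v_now = v
    for i, target in enumerate(targets):
        vc = v + rng.normal(0.0, 0.8)  # lap-to-lap cruise variability
        leg = target - pos
        used = 0.0
        # post-reward epoch of the previous leg (not for the very first leg)
        if i > 0:
            if expert:
                add(1.0, v_app, v_app)  # consumption creep
                add(1.0, v_app, vc)
                used += dist(1.0, v_app, v_app) + dist(1.0, v_app, vc)
            v_now = vc
        # one immobility pause per lap, on the leg that follows the second site
        if cfg.pause_every_lap and i % 2 == 0 and i > 0:
            add(1.0, v_now, 0.0)
            used += dist(1.0, v_now, 0.0)
            add(3.5 + rng.uniform(0.0, 1.0), 0.0, 0.0)
            add(1.5, 0.0, vc)
            used += dist(1.5, 0.0, vc)
            v_now = vc
        if expert:
            decel_d = dist(2.0, vc, v_app)
        else:
            decel_d = 0.0
        cruise_d = leg - used - decel_d
        if cruise_d < 0:
            raise ValueError("leg too short for the configured speed profile")
        add(cruise_d / vc, vc, vc)
        if expert:
            add(2.0, vc, v_app)
            v_now = v_app
        else:
            v_now = vc
        pos = target
        reward_dist.append(target)
    # run out past the last reward
    if expert:
        add(1.0, v_app, v_app)
        add(1.0, v_app, v)
    add(3.0, v, v)
    return segs, np.asarray(reward_dist)


def generate_behavior(cfg: SynthConfig, rng: Optional[np.random.Generator] = None):
    """Generate behavior traces, event table and lap table.

    Returns ``(behavior, events, laps, info)``.  Position advances
    monotonically modulo the track length; reward events are emitted when the
    animal reaches a reward site; licks are an inhomogeneous Poisson process
    whose rate steps per zone (expert: elevated in the 2 s pre-reward zone),
    with a log-normal lap-to-lap intensity factor.  ``info`` carries that
    per-reward licking amplitude so unit modulation can co-vary with it.
    """
    for p in cfg.reward_positions_cm:
        if not (0 <= p < cfg.track_length_cm):
            raise ValueError(f"reward position {p} outside [0, {cfg.track_length_cm})")
    if rng is None:
        rng = child_rng(cfg.seed, "behavior")
    dt = cfg.behavior_dt_s

    if cfg.n_laps == 0:
        behavior = pd.DataFrame({"t": [], "position": [], "speed": []})
        events = pd.DataFrame({"t": [], "kind": pd.Series([], dtype=str),
                               "duration": []})
        laps = pd.DataFrame({"lap": [], "start": [], "end": []})
        return behavior, events, laps, {"reward_lick_amp": np.array([])}

    segs, reward_dist = _segments_for_session(cfg, rng)

    speeds = []
    for dur, v0, v1 in segs:
        n = max(int(round(dur / dt)), 1)
        speeds.append(np.linspace(v0, v1, n, endpoint=False))
    speed = np.concatenate(speeds)
    # measurement noise; immobility stays below the 0.5 cm/s threshold
    noise = rng.normal(0.0, 0.08, speed.size)
    speed_noisy = np.clip(speed + np.where(speed < 0.25, np.abs(noise) * 0.5, noise),
                          0.0, None)
    t = np.arange(speed.size) * dt
    cumdist = np.concatenate([[0.0], np.cumsum(speed_noisy[:-1] * dt)])
    position = np.mod(cumdist, cfg.track_length_cm)

    # reward times: first sample at/after each target distance
    idx = np.searchsorted(cumdist, reward_dist)
    idx = np.clip(idx, 0, t.size - 1)
    reward_times = t[idx]

    # laps from cumulative distance crossings of multiples of the track length
    n_laps_run = int(cumdist[-1] // cfg.track_length_cm)
    bounds = np.searchsorted(
        cumdist, cfg.track_length_cm * np.arange(1, n_laps_run + 1)
    )
    lap_edges = np.concatenate([[0.0], t[np.clip(bounds, 0, t.size - 1)]])
    if lap_edges[-1] < t[-1]:
        lap_edges = np.concatenate([lap_edges, [t[-1] + dt]])
    laps = pd.DataFrame(
        {
            "lap": np.arange(lap_edges.size - 1),
            "start": lap_edges[:-1],
            "end": lap_edges[1:],
        }
    )

    # licks: zone-stepped Poisson rate with lap-to-lap intensity variability
    amps = np.exp(rng.normal(0.0, cfg.lick_amp_sigma, reward_times.size))
    lick_rate = np.full(t.size, cfg.lick_rate_baseline_hz)
    for r, amp in zip(reward_times, amps):
        if cfg.performance == "expert":
            lick_rate[(t >= r - 2.0) & (t < r)] = cfg.lick_rate_pre_hz * amp
        lick_rate[(t >= r) & (t < r + 2.0)] = cfg.lick_rate_post_hz * amp
    lick_times = generate_spike_train(lick_rate, dt, rng)

    events = pd.concat(
        [
            pd.DataFrame({"t": reward_times, "kind": "reward", "duration": 0.0}),
            pd.DataFrame({"t": lick_times, "kind": "lick", "duration": 0.0}),
        ],
        ignore_index=True,
    ).sort_values(["kind", "t"], kind="stable").reset_index(drop=True)

    behavior = pd.DataFrame({"t": t, "position": position, "speed": speed_noisy})
    info = {"reward_lick_amp": amps, "lick_rate": lick_rate, "t": t}
    return behavior, events, laps, info


# --------------------------------------------------------------------------- #
# spike trains
# --------------------------------------------------------------------------- #

def generate_spike_train(
    rate_hz: np.ndarray,
    dt_s: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning.

    ``rate_hz`` is the rate sampled on a uniform grid of step ``dt_s``
    starting at ``t0``; counts in any window are Poisson with mean equal to
    the integrated rate.  Negative rates are rejected.
    """
    rate_hz = np.asarray(rate_hz, dtype=float)
    if rate_hz.size == 0:
        return np.array([], dtype=float)
    if np.any(rate_hz < 0):
        raise ValueError("rate must be non-negative")
    lam_max = float(rate_hz.max())
    duration = rate_hz.size * dt_s
    if lam_max == 0:
        return np.array([], dtype=float)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    accept = rng.uniform(0.0, lam_max, n_cand) < rate_hz[
        np.minimum((cand / dt_s).astype(int), rate_hz.size - 1)
    ]
    return cand[accept] + t0


def inject_synapse(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    efficacy: float,
    latency_ms: float,
    jitter_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add monosynaptically transmitted spikes to a postsynaptic train.

    Each presynaptic spike elicits one postsynaptic spike with probability
    ``efficacy`` at ``latency_ms`` + N(0, ``jitter_ms``); the background
    train is preserved.  Returns the merged, strictly sorted train.
    """
    if not (0 < efficacy <= 1):
        raise ValueError("efficacy must be in (0, 1]")
    if latency_ms <= 0:
        raise ValueError("latency must be positive")
    pre_times = np.asarray(pre_times, dtype=float)
    fired = rng.uniform(size=pre_times.size) < efficacy
    added = pre_times[fired] + latency_ms * 1e-3
    if jitter_ms > 0:
        added = added + rng.normal(0.0, jitter_ms * 1e-3, added.size)
    merged = np.sort(np.concatenate([np.asarray(post_times, float), added]))
    return _enforce_strict(merged)


def _enforce_strict(times: np.ndarray, min_gap_s: float = 1e-4) -> np.ndarray:
    """Drop spikes closer than ``min_gap_s`` to their predecessor (dead time)."""
    if times.size < 2:
        return times
    keep = np.concatenate([[True], np.diff(times) >= min_gap_s])
    return times[keep]


def make_waveform(
    trough_to_peak_ms: float,
    fs_hz: float,
    rng: np.random.Generator,
    n_sites: int = 4,
    n_samples: int = 64,
) -> np.ndarray:
    """Parametric biphasic mean waveform (site x sample), trough-first.

    A negative Gaussian trough followed by a slower positive peak at the
    requested trough-to-peak interval; one dominant site, attenuated copies
    with small independent noise on the others.
    """
    t = np.arange(n_samples) / fs_hz * 1e3  # ms
    t_trough = t[n_samples // 3]
    trough_sd = 0.08 + 0.1 * trough_to_peak_ms
    peak_sd = 0.15 + 0.25 * trough_to_peak_ms
    shape = -100.0 * np.exp(-0.5 * ((t - t_trough) / trough_sd) ** 2) + 45.0 * np.exp(
        -0.5 * ((t - t_trough - trough_to_peak_ms) / peak_sd) ** 2
    )
    atten = np.array([1.0, 0.45, 0.25, 0.12])[:n_sites]
    wf = np.outer(atten, shape)
    wf += rng.normal(0.0, 0.5, wf.shape)
    return wf


# --------------------------------------------------------------------------- #
# light protocol
# --------------------------------------------------------------------------- #

def _pulse_onsets(t_start: float, n: int, isi: float) -> np.ndarray:
    return t_start + isi * np.arange(n)


def apply_light_protocol(
    rate: np.ndarray,
    dt: float,
    spec: OptoSpec,
    dg_onsets: np.ndarray,
    fim_onsets: np.ndarray,
    pulse_dur: float,
) -> np.ndarray:
    """Modify a unit's rate profile for the light-pulse protocol.

    ChR2 units step to ``gain`` x rate during dentate pulses (and fimbria
    pulses when projecting); inhibited units drop to near zero; disinhibited
    units step up only after ``disinh_delay_ms`` so their first
    light-triggered spikes come late (> 5 ms).  Deterministic first spikes
    for ChR2 units are injected separately by the session generator.
    """
    if pulse_dur <= 0:
        raise ValueError("pulse duration must be positive")
    for onsets in (dg_onsets, fim_onsets):
        if onsets.size > 1 and np.any(np.diff(onsets) < pulse_dur):
            raise ValueError("overlapping light pulses")
    rate = rate.copy()
    n = rate.size

    def window(a, b):
        i0, i1 = max(int(np.ceil(a / dt)), 0), min(int(np.ceil(b / dt)), n)
        return slice(i0, i1)

    responds_at = []
    if spec.is_chr2 or spec.is_inhibited or spec.is_disinhibited:
        responds_at.append(dg_onsets)
    if spec.is_chr2 and spec.projects_to_fimbria:
        responds_at.append(fim_onsets)
    for onsets in responds_at:
        for on in onsets:
            if spec.is_chr2:
                rate[window(on, on + pulse_dur)] *= spec.gain
            elif spec.is_inhibited:
                rate[window(on, on + pulse_dur)] *= 0.02
            elif spec.is_disinhibited:
                rate[window(on + spec.disinh_delay_ms * 1e-3, on + pulse_dur)] *= (
                    spec.gain / 2
                )
    return rate


# --------------------------------------------------------------------------- #
# full session
# --------------------------------------------------------------------------- #

def _class_defaults(spec: UnitSpec) -> UnitSpec:
    """Fill burstiness / waveform defaults from the unit class."""
    if spec.unit_class == "PC" and spec.burst_prob == 0.0:
        spec.burst_prob = 0.35
    if spec.unit_class == "PC" and spec.trough_to_peak_ms == 0.6:
        spec.trough_to_peak_ms = 0.70
    if spec.unit_class == "FSI" and spec.trough_to_peak_ms == 0.6:
        spec.trough_to_peak_ms = 0.25
    return spec


def generate_session(cfg: SynthConfig):
    """Compose behavior, light protocol and unit spike trains into a
    :class:`~dgsomi.session.Session` plus a ground-truth manifest.

    Deterministic under ``cfg.seed``.  The manifest lists, per unit, the true
    class, opto category, projection target, reward-modulation profile,
    locomotion category and GC/MC identity, plus every injected synapse —
    enough to score each downstream classifier.
    """
    rng_beh = child_rng(cfg.seed, "behavior")
    behavior, events, laps, beh_info = generate_behavior(cfg, rng_beh)
    lick_amps = beh_info["reward_lick_amp"]
    t_beh = behavior["t"].to_numpy() if len(behavior) else np.array([0.0])
    T_beh = float(t_beh[-1]) + cfg.behavior_dt_s if len(behavior) else 0.0

    # opto period after the behavioral period
    dg_onsets = _pulse_onsets(T_beh + 5.0, cfg.n_pulses_dg, cfg.pulse_isi_s)
    fim_start = (dg_onsets[-1] + cfg.pulse_isi_s) if dg_onsets.size else T_beh + 5.0
    fim_onsets = _pulse_onsets(fim_start, cfg.n_pulses_fimbria, cfg.pulse_isi_s)
    T_opto_end = (fim_onsets[-1] + cfg.pulse_isi_s) if fim_onsets.size else fim_start

    # optional sensory block after the opto period
    sens_events = []
    T_total = T_opto_end
    if cfg.sensory_n_stimuli > 0:
        t0 = T_opto_end + 5.0
        for kind in ("stim_visual", "stim_sound", "stim_airpuff"):
            onsets = t0 + cfg.sensory_isi_s * np.arange(cfg.sensory_n_stimuli)
            sens_events.append(
                pd.DataFrame(
                    {"t": onsets, "kind": kind, "duration": cfg.sensory_duration_s}
                )
            )
            t0 = onsets[-1] + cfg.sensory_isi_s + 2.0
        T_total = t0

    dt = cfg.rate_dt_s
    n_grid = int(np.ceil(T_total / dt)) + 1
    grid_t = np.arange(n_grid) * dt

    reward_times = events.loc[events["kind"] == "reward", "t"].to_numpy()
    speed_on_grid = (
        np.interp(grid_t, t_beh, behavior["speed"].to_numpy(), left=0.0, right=0.0)
        if len(behavior)
        else np.zeros(n_grid)
    )
    pos_on_grid = (
        np.interp(grid_t, t_beh, behavior["position"].to_numpy(), left=0.0, right=0.0)
        if len(behavior)
        else np.zeros(n_grid)
    )
    in_behavior = grid_t < T_beh

    units: list[Unit] = []
    gt_units = []
    for uid, spec in enumerate(cfg.units):
        spec = _class_defaults(spec)
        rng_u = child_rng(cfg.seed, f"unit_{uid}")
        rate = np.full(n_grid, spec.baseline_rate_hz)

        # locomotion-state modulation (behavior period only)
        if spec.locomotion_modulation in ("ON", "OFF"):
            lo, hi = (0.4, 1.6) if spec.locomotion_modulation == "OFF" else (1.6, 0.4)
            frac = np.clip(speed_on_grid / 3.0, 0.0, 1.0)
            factor = lo + (hi - lo) * (1.0 - frac)
            rate = np.where(in_behavior, rate * factor, rate)
        if spec.speed_slope != 0.0:
            rate = np.where(
                in_behavior,
                np.clip(rate + spec.speed_slope * speed_on_grid, 0.0, None),
                rate,
            )

        # lick-locked component (behavior period only)
        if spec.lick_rate_gain != 0.0 and "lick_rate" in beh_info:
            lick_on_grid = np.interp(grid_t, beh_info["t"],
                                     beh_info["lick_rate"], left=0.0, right=0.0)
            rate = np.where(
                in_behavior,
                np.clip(rate + spec.lick_rate_gain * lick_on_grid, 0.0, None),
                rate,
            )

        # place field (multiplicative Gaussian bump on the circular track)
        if spec.place_field is not None:
            c, sd, gain = spec.place_field
            d = np.abs(pos_on_grid - c)
            d = np.minimum(d, cfg.track_length_cm - d)
            bump = 1.0 + (gain - 1.0) * np.exp(-0.5 * (d / sd) ** 2)
            rate = np.where(in_behavior, rate * bump, rate)

        # peri-reward modulation
        rm = spec.reward_modulation
        if rm.profile != "none" and rm.peak_gain != 1.0:
            mod = np.ones(n_grid)
            for k, r in enumerate(reward_times):
                # per-trial amplitude optionally follows the lap's licking
                # intensity (lick_coupling = 0: fixed gain every trial)
                amp = lick_amps[k] ** spec.lick_coupling if lick_amps.size else 1.0
                gain_k = 1.0 + (rm.peak_gain - 1.0) * amp
                if rm.shape == "gaussian":
                    lo_i = max(int((r + rm.peak_time_s - 4 * rm.width_s) / dt), 0)
                    hi_i = min(int((r + rm.peak_time_s + 4 * rm.width_s) / dt), n_grid)
                    tt = grid_t[lo_i:hi_i]
                    mod[lo_i:hi_i] *= 1.0 + (gain_k - 1.0) * np.exp(
                        -0.5 * ((tt - r - rm.peak_time_s) / rm.width_s) ** 2
                    )
                else:  # step
                    a, b = rm.window_s
                    lo_i = max(int(np.ceil((r + a) / dt)), 0)
                    hi_i = min(int(np.ceil((r + b) / dt)), n_grid)
                    mod[lo_i:hi_i] *= gain_k
            rate = rate * mod

        # sensory responses
        for df in sens_events:
            kind = df["kind"].iloc[0]
            g = spec.sensory_gain.get(kind, 1.0)
            if g != 1.0:
                for on in df["t"]:
                    i0 = int(np.ceil(on / dt))
                    i1 = int(np.ceil((on + cfg.sensory_duration_s) / dt))
                    rate[i0:i1] *= g

        # light protocol
        rate = apply_light_protocol(
            rate, dt, spec.opto, dg_onsets, fim_onsets, cfg.pulse_duration_s
        )

        spikes = generate_spike_train(np.clip(rate, 0.0, None), dt, rng_u)

        # deterministic first light-triggered spike for ChR2 units
        if spec.opto.is_chr2:
            lat = spec.opto.latency_ms * 1e-3
            det = dg_onsets + lat + rng_u.normal(0.0, 1e-4, dg_onsets.size)
            if spec.opto.projects_to_fimbria:
                det = np.concatenate(
                    [det, fim_onsets + lat + rng_u.normal(0.0, 1e-4, fim_onsets.size)]
                )
            spikes = np.sort(np.concatenate([spikes, det]))

        # burst doublets for bursty (PC-class) units
        if spec.burst_prob > 0 and spikes.size:
            fired = rng_u.uniform(size=spikes.size) < spec.burst_prob
            doublets = spikes[fired] + 4e-3 + rng_u.normal(0.0, 3e-4, int(fired.sum()))
            spikes = np.sort(np.concatenate([spikes, doublets]))

        spikes = _enforce_strict(spikes)
        spikes = spikes[(spikes >= 0) & (spikes < T_total)]

        wf = make_waveform(
            spec.trough_to_peak_ms + rng_u.normal(0.0, 0.015), 30_000.0, rng_u
        )
        units.append(
            Unit(
                unit_id=uid,
                spike_times=spikes,
                waveform=wf,
                waveform_fs_hz=30_000.0,
                features={"ds_amplitude": spec.ds_amplitude},
            )
        )
        opto_cat = (
            "SOMI"
            if spec.opto.is_chr2
            else "SOM_inh"
            if spec.opto.is_inhibited
            else "SOM_disinh"
            if spec.opto.is_disinhibited
            else "NONE"
        )
        gt_units.append(
            {
                "unit_id": uid,
                "unit_class": spec.unit_class,
                "opto": opto_cat,
                "projection": (
                    ("proj" if spec.opto.projects_to_fimbria else "local")
                    if opto_cat == "SOMI"
                    else "NA"
                ),
                "reward_profile": rm.profile,
                "locomotion": spec.locomotion_modulation,
                "gc_mc": spec.gc_mc,
                "baseline_rate_hz": spec.baseline_rate_hz,
            }
        )

    # monosynaptic coupling
    for syn in cfg.synapses:
        rng_s = child_rng(cfg.seed, f"synapse_{syn.pre_id}_{syn.post_id}")
        post = units[syn.post_id]
        post.spike_times = inject_synapse(
            units[syn.pre_id].spike_times,
            post.spike_times,
            syn.efficacy,
            syn.latency_ms,
            syn.jitter_ms,
            rng_s,
        )

    # event table incl. light pulses and sensory stimuli
    parts = [events]
    if dg_onsets.size:
        parts.append(
            pd.DataFrame(
                {"t": dg_onsets, "kind": "light_dg", "duration": cfg.pulse_duration_s}
            )
        )
    if fim_onsets.size:
        parts.append(
            pd.DataFrame(
                {
                    "t": fim_onsets,
                    "kind": "light_fimbria",
                    "duration": cfg.pulse_duration_s,
                }
            )
        )
    parts.extend(sens_events)
    all_events = (
        pd.concat(parts, ignore_index=True)
        .sort_values(["kind", "t"], kind="stable")
        .reset_index(drop=True)
    )

    session = Session(
        units=units,
        behavior=behavior,
        events=all_events,
        laps=laps,
        meta={
            "track_length_cm": cfg.track_length_cm,
            "performance": cfg.performance,
            "behavior_end_s": T_beh,
            "seed": cfg.seed,
        },
    )
    ground_truth = {
        "performance": cfg.performance,
        "units": gt_units,
        "synapses": [asdict(s) for s in cfg.synapses],
        "n_laps": cfg.n_laps,
        "seed": cfg.seed,
    }
    return session, ground_truth


# --------------------------------------------------------------------------- #
# default study configurations
# --------------------------------------------------------------------------- #

def _default_units(performance: str) -> list[UnitSpec]:
    """12 SOMIs, 20 principal cells, 6 fast-spiking interneurons.

    Expert cohorts carry a predictive-SOMI majority (8 predictive / 4
    consumption); non-expert SOMIs all peak after reward onset.  Most units
    are reward-modulated, mirroring recordings at learned goal sites; place
    fields sit away from the peri-reward windows so unmodulated units stay
    genuinely unmodulated.
    """
    expert = performance == "expert"
    units: list[UnitSpec] = []

    pred = RewardModulation("predictive", "gaussian", 3.0, -0.3, 0.5)
    cons = RewardModulation("consumption", "gaussian", 3.0, 1.2, 0.4)
    locomotion = ["OFF"] * 5 + ["ON"] * 3 + ["NON"] * 4
    for i in range(12):
        profile = (pred if i < 8 else cons) if expert else cons
        units.append(
            UnitSpec(
                unit_class="WI",
                baseline_rate_hz=8.0,
                reward_modulation=RewardModulation(**asdict(profile)),
                locomotion_modulation=locomotion[i],
                opto=OptoSpec(
                    is_chr2=True,
                    latency_ms=1.5 + 0.2 * i,
                    projects_to_fimbria=(i < 3),
                ),
                trough_to_peak_ms=0.60,
                ds_amplitude=0.0,
                lick_coupling=1.0,
                # predictive SOMIs track anticipatory licking directly
                lick_rate_gain=0.8 if profile.profile == "predictive" else 0.0,
            )
        )

    # principal cells: 10 GC-like (sparse, strong place fields, high spatial
    # information, large resting dentate-spike amplitude) and 10 MC-like
    safe_centers = np.concatenate([np.linspace(142, 168, 10),
                                   np.linspace(342, 368, 10)])
    for i in range(20):
        gc = i < 10
        profile = (
            RewardModulation("consumption", "gaussian", 2.5, 1.2, 0.4)
            if i % 20 < 12
            else RewardModulation("predictive", "gaussian", 2.5, -0.3, 0.5)
            if i % 20 < 16
            else RewardModulation()
        )
        units.append(
            UnitSpec(
                unit_class="PC",
                baseline_rate_hz=1.2 if gc else 4.0,
                reward_modulation=profile,
                locomotion_modulation="NON",
                opto=OptoSpec(is_inhibited=(i < 4), is_disinhibited=(4 <= i < 6)),
                place_field=(float(safe_centers[i]), 12.0, 6.0 if gc else 1.6),
                ds_amplitude=1.5 if gc else 0.5,
                gc_mc="putative_GC" if gc else "putative_MC",
            )
        )

    for i in range(6):
        units.append(
            UnitSpec(
                unit_class="FSI",
                baseline_rate_hz=15.0,
                reward_modulation=(
                    RewardModulation("consumption", "gaussian", 2.0, 1.0, 0.4)
                    if i < 4
                    else RewardModulation()
                ),
                locomotion_modulation="NON",
                speed_slope=0.3 if i < 3 else 0.0,
                ds_amplitude=0.5,
            )
        )
    return units


def default_expert_config(seed: int = 0, n_laps: int = 30) -> SynthConfig:
    """The default expert study session: 38 units, 30 laps, dual-site light
    protocol, three PC->SOMI synapses."""
    units = _default_units("expert")
    synapses = [
        SynapseSpec(pre_id=12, post_id=0, efficacy=0.3, latency_ms=2.0),
        SynapseSpec(pre_id=13, post_id=1, efficacy=0.3, latency_ms=2.5),
        SynapseSpec(pre_id=22, post_id=2, efficacy=0.3, latency_ms=3.0),
    ]
    return SynthConfig(
        n_laps=n_laps, performance="expert", units=units, synapses=synapses, seed=seed
    )


def decoder_benchmark_config(
    seed: int = 0,
    n_cells: int = 10,
    n_trials: int = 30,
    gain: float = 2.0,
    baseline_rate_hz: float = 5.0,
) -> SynthConfig:
    """Expert cohort for the population-decoding benchmark: ``n_cells``
    reward-anticipatory SOMIs whose rate steps by ``gain`` during the 1.5 s
    before each reward delivery, ``n_trials`` rewarded trials, no light
    protocol (decoding needs only the behavioral period)."""
    units = [
        UnitSpec(
            unit_class="WI",
            baseline_rate_hz=baseline_rate_hz,
            reward_modulation=RewardModulation(
                "predictive", "step", gain, window_s=(-1.5, 0.0)
            ),
        )
        for _ in range(n_cells)
    ]
    return SynthConfig(
        n_laps=(n_trials + 1) // 2, performance="expert", units=units,
        n_pulses_dg=0, n_pulses_fimbria=0, seed=seed,
    )


def default_nonexpert_config(seed: int = 1, n_laps: int = 30) -> SynthConfig:
    units = _default_units("nonexpert")
    return SynthConfig(
        n_laps=n_laps, performance="nonexpert", units=units, synapses=[], seed=seed
    )
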