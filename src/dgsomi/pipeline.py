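"""End-to-end session pipeline.

Runs the stages in dependency order — behavior -> unit classification ->
opto-tagging -> connectivity -> event responses -> GLM -> decoder — and
collects a JSON-serializable report plus per-stage tables.  Identical
(config, session) input yields identical output; any stage failure aborts
with the stage name.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import connectivity as conn
from . import decoder as dec
from . import events as ev
from . import glm as glm_mod
from . import optotag as opto
from . import units as uc
from .config import PipelineConfig
from .rng import child_seed
from .session import Session

__all__ = ["run_pipeline"]

log = logging.getLogger("dgsomi")


class StageError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage '{name}' failed: {e}") from e
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("behavior")
def _run_behavior(cfg: PipelineConfig, session: Session) -> dict:
    b = session.behavior
    segs = beh.segment_motion(
        b["t"].to_numpy(), b["speed"].to_numpy(),
        cfg.immobility_speed_cms, cfg.locomotion_speed_cms,
        cfg.min_immobility_s, cfg.max_transition_s,
    )
    zr = beh.zone_rates(
        session.event_times("lick"), b, session.reward_times,
        cfg.baseline_window_s,
        (-cfg.pre_zone_s, 0.0), (0.0, cfg.post_zone_s),
    )
    verdict = beh.classify_performance(zr, cfg.behavior_alpha, cfg.min_rewarded_laps)
    score = beh.performance_score(zr)
    trend = beh.lick_lap_trend(zr["lick_pre"].to_numpy())
    return {
        "segments": segs, "zone_rates": zr, "verdict": verdict,
        "performance_score": score, "lick_lap_trend": trend,
    }


@_stage("classify")
def _run_classify(cfg: PipelineConfig, session: Session) -> pd.DataFrame:
    rows = []
    end = session.meta.get("behavior_end_s", session.duration_s)
    wfs = [u.waveform for u in session.units]
    fss = [u.waveform_fs_hz for u in session.units]
    pcs = uc.waveform_pcs(wfs, fss[0]) if session.units else np.zeros((0, 2))
    for i, u in enumerate(session.units):
        lags, counts, ok = uc.autocorrelogram(
            u.spike_times, cfg.acg_bin_ms, cfg.acg_max_lag_ms
        )
        bi, bi_ok = uc.bursting_index(lags, counts)
        ttp = uc.trough_to_peak(u.waveform, u.waveform_fs_hz)
        label = uc.classify_unit(
            bi, ttp, ok and bi_ok,
            cfg.bursting_threshold, cfg.trough_to_peak_threshold_ms,
        )
        rmap, occ = uc.rate_map(
            u.spike_times, session.behavior,
            session.meta.get("track_length_cm", 400.0), t_max=end,
        )
        si = uc.spatial_information(rmap, np.maximum(occ, 1e-12))
        u.features.update(
            bursting_index=bi, trough_to_peak_ms=ttp, spatial_information=si,
            w_pc1=float(pcs[i, 0]), w_pc2=float(pcs[i, 1]),
        )
        u.labels["class"] = label
        rows.append(
            {"unit_id": u.unit_id, "bursting_index": bi, "trough_to_peak_ms": ttp,
             "class": label, "spatial_information": si,
             "mean_rate_hz": u.n_spikes / max(session.duration_s, 1e-9),
             "w_pc1": pcs[i, 0], "w_pc2": pcs[i, 1],
             "ds_amplitude": u.features.get("ds_amplitude", np.nan)}
        )
    table = pd.DataFrame(rows)

    # GC/MC split of the PC class
    pc_rows = table[table["class"] == "PC"]
    table["gc_mc"] = "NA"
    if len(pc_rows) >= 4:
        feats = pc_rows[["w_pc1", "w_pc2", "ds_amplitude", "spatial_information"]]
        labels, flags = uc.cluster_gc_mc(
            feats.to_numpy(), pc_rows["spatial_information"].to_numpy(),
            pc_rows["mean_rate_hz"].to_numpy(),
            cfg.kmeans_restarts, child_seed(cfg.seed, "kmeans"),
        )
        table.loc[pc_rows.index, "gc_mc"] = labels
        for uid, lab in zip(pc_rows["unit_id"], labels):
            session.unit_by_id(int(uid)).labels["gc_mc"] = lab
    return table


@_stage("optotag")
def _run_optotag(cfg: PipelineConfig, session: Session) -> pd.DataFrame:
    dg = session.event_rows("light_dg")
    fim = session.event_rows("light_fimbria")
    rows = []
    for u in session.units:
        resp_dg = opto.light_response(
            u.spike_times, dg["t"].to_numpy(), float(dg["duration"].iloc[0]),
            cfg.opto_alpha, cfg.opto_min_pulses, late_increase_check=True,
        )
        tag = opto.tag_unit(resp_dg, cfg.somi_latency_ms)
        resp_fim = None
        if len(fim) >= cfg.opto_min_pulses:
            resp_fim = opto.light_response(
                u.spike_times, fim["t"].to_numpy(), float(fim["duration"].iloc[0]),
                cfg.opto_alpha, cfg.opto_min_pulses,
            )
        proj = opto.subtype_projection(tag, resp_fim)
        u.labels["opto"] = tag
        u.labels["projection"] = proj
        rows.append(
            {"unit_id": u.unit_id, "opto": tag, "projection": proj,
             "p_dg": resp_dg.p_value, "direction_dg": resp_dg.direction,
             "median_latency_ms": resp_dg.median_first_latency_ms,
             "p_fimbria": resp_fim.p_value if resp_fim else np.nan,
             "somi_inhibited_by_somi":
                 "early_increase_late_decrease" in resp_dg.flags}
        )
    return pd.DataFrame(rows)


@_stage("connect")
def _run_connectivity(cfg: PipelineConfig, session: Session) -> pd.DataFrame:
    """Screen PC -> (SOMI or WI) pairs for monosynaptic excitation."""
    rows = []
    pre_units = [u for u in session.units if u.labels.get("class") == "PC"]
    post_units = [
        u for u in session.units
        if u.labels.get("opto") == "SOMI" or u.labels.get("class") in ("WI", "FSI")
    ]
    for pre in pre_units:
        for post in post_units:
            if pre.unit_id == post.unit_id:
                continue
            ccg = conn.cross_correlogram(
                pre.spike_times, post.spike_times, cfg.ccg_bin_ms, cfg.ccg_max_lag_ms
            )
            if "empty_train" in ccg.flags:
                continue
            ccg = conn.detect_connection(
                ccg, bin_ms=cfg.ccg_bin_ms, causal_window_ms=cfg.causal_window_ms,
                quantile=cfg.ccg_quantile, sigma_ms=cfg.ccg_kernel_sigma_ms,
                hollow_fraction=cfg.ccg_hollow_fraction,
            )
            rows.append(
                {"pre_id": pre.unit_id, "post_id": post.unit_id,
                 "connected": ccg.connected, "latency_ms": ccg.latency_ms,
                 "causal_peak": ccg.causal_peak_count,
                 "anticausal_peak": ccg.anticausal_peak_count,
                 "borderline": "borderline" in ccg.flags}
            )
    return pd.DataFrame(rows)


@_stage("events")
def _run_events(cfg: PipelineConfig, session: Session, segments) -> dict:
    rewards = session.reward_times
    trans = segments.transitions
    onsets = trans.loc[trans["kind"] == "onset", "t"].to_numpy()
    offsets = trans.loc[trans["kind"] == "offset", "t"].to_numpy()
    end = session.meta.get("behavior_end_s", session.duration_s)
    mod_rows, onoff_rows, speed_rows = [], [], []
    delays = {}
    for u in session.units:
        mod = ev.reward_modulation(
            u.spike_times, rewards, cfg.baseline_window_s,
            (-cfg.pre_zone_s, 0.0), (0.0, cfg.post_zone_s),
            cfg.modulation_alpha, cfg.min_modulation_trials,
        )
        mod_rows.append({"unit_id": u.unit_id, **mod})
        if mod["classification"] != "unmodulated":
            aligned = ev.align(u.spike_times, rewards, cfg.align_window_s,
                               cfg.align_bin_s, recording_end_s=end)
            try:
                delays[u.unit_id] = ev.delay_to_max_change(
                    aligned, cfg.delay_search_window_s, cfg.baseline_window_s,
                    cfg.smooth_sigma_bins,
                )
            except ValueError:
                delays[u.unit_id] = float("nan")
        oo = ev.onoff_classify(
            u.spike_times, onsets, offsets,
            cfg.onoff_windows_s[:2], cfg.onoff_windows_s[2:],
            cfg.modulation_alpha, cfg.onoff_min_transitions,
        )
        onoff_rows.append({"unit_id": u.unit_id,
                           "onoff": oo["classification"]})
        try:
            sr = ev.speed_regression(
                u.spike_times, session.behavior, cfg.speed_regression_bin_s,
                steady_state_only=True, run_thr_cms=cfg.locomotion_speed_cms,
                t_max=end,
            )
        except ValueError:
            sr = {"slope": np.nan, "r": np.nan, "p": np.nan}
        speed_rows.append({"unit_id": u.unit_id, "speed_slope": sr["slope"],
                           "speed_r": sr["r"], "speed_p": sr["p"]})
    # sensory stimuli, when present
    sens = session.events[session.events["kind"].str.startswith("stim_")]
    sensory = {}
    if len(sens):
        for u in session.units:
            sensory[u.unit_id] = ev.sensory_response(
                u.spike_times, sens, cfg.modulation_alpha, cfg.sensory_min_events
            )
    return {
        "modulation": pd.DataFrame(mod_rows),
        "delays": delays,
        "onoff": pd.DataFrame(onoff_rows),
        "speed_regression": pd.DataFrame(speed_rows),
        "sensory": sensory,
    }


@_stage("glm")
def _run_glm(cfg: PipelineConfig, session: Session, unit_ids) -> pd.DataFrame:
    rewards = session.reward_times
    licks = session.event_times("lick")
    rows = []
    for uid in unit_ids:
        u = session.unit_by_id(uid)
        design = glm_mod.build_design(
            u.spike_times, session.behavior, licks, rewards,
            cfg.glm_window_s, cfg.glm_n_bins,
        )
        fit = glm_mod.permutation_test(
            design, cfg.glm_n_permutations, cfg.glm_quantile, cfg.glm_folds,
            seed=child_seed(cfg.seed, f"glm_{uid}"),
        )
        rows.append(
            {"unit_id": uid, "ev": fit.ev, "significant": fit.significant,
             "null_q95": fit.null_quantile,
             **{f"delta_ev_{k}": v for k, v in fit.delta_ev.items()}}
        )
    return pd.DataFrame(rows)


@_stage("decode")
def _run_decoder(cfg: PipelineConfig, session: Session, unit_ids) -> dict:
    rewards = session.reward_times
    end = session.meta.get("behavior_end_s", session.duration_s)
    # rate-based inclusion: > 1 spike / 1.5 s on average
    cells, kept = [], []
    for uid in unit_ids:
        u = session.unit_by_id(uid)
        n_beh = np.searchsorted(u.spike_times, end)
        if n_beh / max(end, 1e-9) >= cfg.min_decoder_rate_hz:
            cells.append(u.spike_times)
            kept.append(uid)
    if not cells:
        return {"flags": ["no_cells_above_rate_floor"]}
    single = {}
    for uid, st in zip(kept, cells):
        res = dec.decode_single(
            st, rewards, cfg.decode_lengths_s,
            baseline_period=cfg.baseline_period_s,
            expectation_window=cfg.expectation_window_s,
            bandwidth_s=cfg.kde_bandwidth_s, grid_s=cfg.kde_grid_s,
            bin_s=cfg.loglik_bin_s, floor_hz=cfg.rate_floor_hz,
            n_shuffles=cfg.decode_n_shuffles,
            shuffle_quantile=cfg.decode_shuffle_quantile,
            seed=child_seed(cfg.seed, f"decode_{uid}"),
        )
        single[uid] = {"accuracy": res.accuracy,
                       "min_significant_L": res.min_significant_L}
    pop = dec.decode_population(
        cells, rewards, L=1.5,
        subset_sizes=sorted({1, min(5, len(cells)), min(10, len(cells)),
                             len(cells)}),
        n_draws=cfg.decode_subset_draws,
        seed=child_seed(cfg.seed, "decode_population"),
        baseline_period=cfg.baseline_period_s,
        expectation_window=cfg.expectation_window_s,
        bandwidth_s=cfg.kde_bandwidth_s, grid_s=cfg.kde_grid_s,
        bin_s=cfg.loglik_bin_s, floor_hz=cfg.rate_floor_hz,
        n_shuffles=50, shuffle_quantile=cfg.decode_shuffle_quantile,
    )
    return {"single": single, "population": pop, "kept_units": kept}


def run_pipeline(cfg: PipelineConfig, session: Session) -> dict:
    """Run the full analysis on one session; returns the report dict.

    SOMI-tagged units feed the GLM and decoder stages.  Stages that lack
    their required events (for example a session without light pulses) are
    skipped and flagged in the report.
    """
    report: dict = {"config": cfg.to_dict()}
    b = _run_behavior(cfg, session)
    report["behavior"] = {
        "verdict": b["verdict"], "performance_score": b["performance_score"],
        "lick_lap_trend": b["lick_lap_trend"],
        "n_transitions": int(len(b["segments"].transitions)),
    }
    report["tables"] = {"zone_rates": b["zone_rates"]}

    classify = _run_classify(cfg, session)
    report["tables"]["units"] = classify

    if len(session.event_rows("light_dg")) >= cfg.opto_min_pulses:
        tags = _run_optotag(cfg, session)
        report["tables"]["optotag"] = tags
        somis = [int(u) for u in tags.loc[tags["opto"] == "SOMI", "unit_id"]]
    else:
        report["optotag_skipped"] = True
        somis = []

    pairs = _run_connectivity(cfg, session)
    report["tables"]["connectivity"] = pairs

    evr = _run_events(cfg, session, b["segments"])
    report["tables"]["modulation"] = evr["modulation"]
    report["tables"]["onoff"] = evr["onoff"]
    report["tables"]["speed_regression"] = evr["speed_regression"]
    report["delays"] = evr["delays"]

    if somis and len(session.reward_times) >= cfg.min_modulation_trials:
        report["tables"]["glm"] = _run_glm(cfg, session, somis)
        report["decoder"] = _run_decoder(cfg, session, somis)
    else:
        report["glm_decoder_skipped"] = True
    return report


def report_to_json(report: dict, path: str | Path) -> Path:
    """Serialize a pipeline report (tables become records) to JSON."""
    def conv(x):
        if isinstance(x, pd.DataFrame):
            return json.loads(x.to_json(orient="records"))
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, dict):
            return {str(k): conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, (bool, int, float, str)) or x is None:
            return x
        return str(x)

    path = Path(path)
    path.write_text(json.dumps(conv(report), indent=1, sort_keys=True))
    return path
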