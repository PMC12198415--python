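"""Session bundle serialization.

A bundle is a directory of plain columnar tables plus a JSON manifest —
inspectable, language-agnostic and diff-able:

    bundle/
      manifest.json     session metadata, unit ids, waveform shape/fs
      behavior.csv      t, position, speed
      events.csv        t, kind, duration
      laps.csv          lap, start, end
      spikes.csv        unit_id, t          (long format, all units)
      waveforms.csv     unit_id, site, <one column per sample>
      unit_features.csv unit_id + any derived feature/label columns (optional)

Floats are written with 9 significant digits, enough to round-trip the
pipeline's statistics bit-stably in practice while keeping files diff-able.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .session import Session, SessionError, Unit

__all__ = ["read_session", "write_session"]

_FLOAT_FMT = "%.9g"


def write_session(session: Session, path: str | Path) -> Path:
    """Write ``session`` as a bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    session.behavior.to_csv(path / "behavior.csv", index=False, float_format=_FLOAT_FMT)
    session.events.to_csv(path / "events.csv", index=False, float_format=_FLOAT_FMT)
    session.laps.to_csv(path / "laps.csv", index=False, float_format=_FLOAT_FMT)

    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(
                [np.full(u.n_spikes, u.unit_id, dtype=int) for u in session.units]
            )
            if session.units
            else np.array([], dtype=int),
            "t": np.concatenate([u.spike_times for u in session.units])
            if session.units
            else np.array([], dtype=float),
        }
    )
    spikes.to_csv(path / "spikes.csv", index=False, float_format=_FLOAT_FMT)

    wf_rows = []
    for u in session.units:
        for site in range(u.waveform.shape[0]):
            wf_rows.append(
                {"unit_id": u.unit_id, "site": site}
                | {f"s{i}": v for i, v in enumerate(u.waveform[site])}
            )
    pd.DataFrame(wf_rows).to_csv(
        path / "waveforms.csv", index=False, float_format=_FLOAT_FMT
    )

    feat_rows = []
    for u in session.units:
        row: dict = {"unit_id": u.unit_id}
        row.update({f"feat_{k}": v for k, v in sorted(u.features.items())})
        row.update({f"label_{k}": v for k, v in sorted(u.labels.items())})
        feat_rows.append(row)
    pd.DataFrame(feat_rows).to_csv(
        path / "unit_features.csv", index=False, float_format=_FLOAT_FMT
    )

    manifest = {
        "format": "dgsomi-bundle-v1",
        "meta": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in session.meta.items()
        },
        "units": [
            {
                "unit_id": u.unit_id,
                "n_spikes": u.n_spikes,
                "waveform_shape": list(u.waveform.shape),
                "waveform_fs_hz": u.waveform_fs_hz,
            }
            for u in session.units
        ],
        "n_events": int(len(session.events)),
        "n_laps": int(len(session.laps)),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_session(path: str | Path) -> Session:
    """Load a bundle directory written by :func:`write_session`.

    Raises :class:`SessionError` naming the offending table or record when an
    invariant is violated.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SessionError(f"no manifest.json in {path}")
    manifest = json.loads(manifest_path.read_text())

    for fname in ("behavior.csv", "events.csv", "laps.csv", "spikes.csv",
                  "waveforms.csv"):
        if not (path / fname).exists():
            raise SessionError(f"bundle missing table {fname}")

    behavior = pd.read_csv(path / "behavior.csv").astype(
        {"t": float, "position": float, "speed": float}
    )
    events = pd.read_csv(path / "events.csv")
    if len(events) == 0:
        events = pd.DataFrame({"t": [], "kind": pd.Series([], dtype=str),
                               "duration": []})
    events = events.astype({"t": float, "duration": float, "kind": str})
    laps = pd.read_csv(path / "laps.csv")
    if len(laps) == 0:
        laps = pd.DataFrame({"lap": [], "start": [], "end": []})
    laps = laps.astype({"lap": int, "start": float, "end": float})
    spikes = pd.read_csv(path / "spikes.csv")
    waveforms = pd.read_csv(path / "waveforms.csv")

    feat_path = path / "unit_features.csv"
    feats = pd.read_csv(feat_path) if feat_path.exists() else pd.DataFrame()

    units = []
    for entry in manifest["units"]:
        uid = int(entry["unit_id"])
        st = spikes.loc[spikes["unit_id"] == uid, "t"].to_numpy(dtype=float)
        wf_block = waveforms[waveforms["unit_id"] == uid].sort_values("site")
        n_sites, n_samples = entry["waveform_shape"]
        cols = [f"s{i}" for i in range(n_samples)]
        wf = wf_block[cols].to_numpy(dtype=float)
        if wf.shape != (n_sites, n_samples):
            raise SessionError(
                f"unit {uid}: waveform shape {wf.shape} != manifest "
                f"{(n_sites, n_samples)}"
            )
        features: dict = {}
        labels: dict = {}
        if len(feats) and uid in set(feats["unit_id"]):
            row = feats[feats["unit_id"] == uid].iloc[0]
            for col, val in row.items():
                if col.startswith("feat_") and pd.notna(val):
                    features[col[5:]] = float(val)
                elif col.startswith("label_") and pd.notna(val):
                    labels[col[6:]] = val
        units.append(
            Unit(
                unit_id=uid,
                spike_times=st,
                waveform=wf,
                waveform_fs_hz=float(entry["waveform_fs_hz"]),
                features=features,
                labels=labels,
            )
        )

    meta = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in manifest.get("meta", {}).items()
    }
    return Session(units=units, behavior=behavior, events=events, laps=laps, meta=meta)
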