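"""Readers and writers for session containers and coupling reports.

Two session dialects are supported:

* **HDF5** (``.h5``/``.hdf5``): groups ``/spikes/<id>`` (dataset ``times``
  with attrs ``region``, ``unit_kind``), ``/events/<n>`` (dataset
  ``onsets`` with attrs ``label``, ``pulse_width``, ``isi``),
  ``/lfp/<region>`` (dataset ``values`` with attrs ``fs``, ``t0``,
  ``kind``); root attrs ``duration``, ``condition``; optional root attr
  ``ground_truth`` holding generator parameters as a JSON string.
* **CSV directory**: ``meta.json`` plus one CSV per spike train
  (``spikes_<id>.csv``, column ``time``), per event series
  (``events_<n>.csv``, column ``onset``) and per LFP
  (``lfp_<region>.csv``, column ``value``); all scalar metadata lives in
  ``meta.json``.

Reports are written as JSON (machine) and Markdown (human); the JSON file
round-trips through :func:`read_report`.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from .types import (
    CouplingReport,
    EventSeries,
    FormatError,
    Session,
    SpikeTrain,
    UniformSignal,
)

__all__ = ["read_session", "write_session", "write_report", "read_report"]


def _is_hdf5_path(path: str) -> bool:
    return str(path).endswith((".h5", ".hdf5"))


def write_session(session: Session, path: str) -> None:
    """Write *session* losslessly (times at double precision)."""
    if _is_hdf5_path(path):
        _write_h5(session, path)
    else:
        _write_csvdir(session, path)


def read_session(path: str) -> Session:
    """Read a session container; all domain invariants are re-enforced."""
    if _is_hdf5_path(path):
        return _read_h5(path)
    if os.path.isdir(path):
        return _read_csvdir(path)
    raise FormatError(f"{path}: not an .h5 file or a session directory")


def _write_h5(session: Session, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["duration"] = float(session.duration)
        f.attrs["condition"] = session.condition
        if session.ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(session.ground_truth)
        g = f.create_group("spikes")
        for tr in session.spike_trains:
            d = g.create_dataset(tr.id or f"train{id(tr)}", data=tr.times, dtype="f8")
            d.attrs["region"] = tr.region
            d.attrs["unit_kind"] = tr.unit_kind
        g = f.create_group("events")
        for k, ev in enumerate(session.events):
            d = g.create_dataset(str(k), data=ev.onsets, dtype="f8")
            d.attrs["label"] = ev.label
            d.attrs["pulse_width"] = float(ev.pulse_width)
            d.attrs["isi"] = float(ev.isi)
        g = f.create_group("lfp")
        for region, sig in session.lfp.items():
            d = g.create_dataset(region, data=sig.values, dtype="f8")
            d.attrs["fs"] = float(sig.fs)
            d.attrs["t0"] = float(sig.t0)
            d.attrs["kind"] = sig.kind


def _read_h5(path: str) -> Session:
    with h5py.File(path, "r") as f:
        if "duration" not in f.attrs:
            raise FormatError(f"{path}: missing required root attr 'duration'")
        gt = f.attrs.get("ground_truth")
        trains = []
        for name, d in f.get("spikes", {}).items():
            trains.append(
                SpikeTrain(
                    times=np.asarray(d[()], dtype=float),
                    region=str(d.attrs["region"]),
                    unit_kind=str(d.attrs.get("unit_kind", "SU")),
                    id=name,
                )
            )
        events = []
        for name in sorted(f.get("events", {}), key=lambda s: int(s)):
            d = f["events"][name]
            events.append(
                EventSeries(
                    onsets=np.asarray(d[()], dtype=float),
                    pulse_width=float(d.attrs["pulse_width"]),
                    isi=float(d.attrs["isi"]),
                    label=str(d.attrs["label"]),
                )
            )
        lfp = {}
        for region, d in f.get("lfp", {}).items():
            lfp[region] = UniformSignal(
                values=np.asarray(d[()], dtype=float),
                fs=float(d.attrs["fs"]),
                t0=float(d.attrs.get("t0", 0.0)),
                kind=str(d.attrs.get("kind", "lfp_raw")),
            )
        return Session(
            duration=float(f.attrs["duration"]),
            spike_trains=trains,
            events=events,
            lfp=lfp,
            condition=str(f.attrs.get("condition", "naive")),
            ground_truth=json.loads(gt) if gt is not None else None,
        )


def _write_csvdir(session: Session, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    meta = {
        "duration": session.duration,
        "condition": session.condition,
        "ground_truth": session.ground_truth,
        "spike_trains": [],
        "events": [],
        "lfp": {},
    }
    for tr in session.spike_trains:
        fname = f"spikes_{tr.id}.csv"
        pd.DataFrame({"time": tr.times}).to_csv(
            os.path.join(path, fname), index=False, float_format="%.17g"
        )
        meta["spike_trains"].append(
            {"id": tr.id, "region": tr.region, "unit_kind": tr.unit_kind, "file": fname}
        )
    for k, ev in enumerate(session.events):
        fname = f"events_{k}.csv"
        pd.DataFrame({"onset": ev.onsets}).to_csv(
            os.path.join(path, fname), index=False, float_format="%.17g"
        )
        meta["events"].append(
            {"label": ev.label, "pulse_width": ev.pulse_width, "isi": ev.isi, "file": fname}
        )
    for region, sig in session.lfp.items():
        fname = f"lfp_{region}.csv"
        pd.DataFrame({"value": sig.values}).to_csv(
            os.path.join(path, fname), index=False, float_format="%.17g"
        )
        meta["lfp"][region] = {"fs": sig.fs, "t0": sig.t0, "kind": sig.kind, "file": fname}
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def _read_csvdir(path: str) -> Session:
    meta_path = os.path.join(path, "meta.json")
    if not os.path.exists(meta_path):
        raise FormatError(f"{path}: missing meta.json")
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in ("duration", "spike_trains", "events", "lfp"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing required field {key!r}")

    def col(fname, name):
        df = pd.read_csv(os.path.join(path, fname), float_precision="round_trip")
        return df[name].to_numpy(dtype=float) if len(df) else np.empty(0)

    trains = [
        SpikeTrain(col(m["file"], "time"), m["region"], m.get("unit_kind", "SU"), m["id"])
        for m in meta["spike_trains"]
    ]
    events = [
        EventSeries(col(m["file"], "onset"), m["pulse_width"], m["isi"], m["label"])
        for m in meta["events"]
    ]
    lfp = {
        region: UniformSignal(col(m["file"], "value"), m["fs"], m.get("t0", 0.0), m["kind"])
        for region, m in meta["lfp"].items()
    }
    return Session(
        duration=float(meta["duration"]),
        spike_trains=trains,
        events=events,
        lfp=lfp,
        condition=meta.get("condition", "naive"),
        ground_truth=meta.get("ground_truth"),
    )


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def write_report(report: CouplingReport, path: str) -> None:
    """Write *report* as JSON; a sibling ``.md`` Markdown table is written too.

    Absent analyses serialize as explicit JSON ``null``.
    """
    payload = _jsonable(asdict(report))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    md_path = os.path.splitext(path)[0] + ".md"
    lines = ["| field | value |", "| --- | --- |"]
    for key, val in payload.items():
        lines.append(f"| {key} | {json.dumps(val)} |")
    with open(md_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_report(path: str) -> CouplingReport:
    with open(path) as fh:
        payload = json.load(fh)
    return CouplingReport(**payload)
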