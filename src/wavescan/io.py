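"""Reading and writing recordings and derived objects.

Two on-disk layouts are supported:

``hdf5``
    A single ``.h5`` file: ``/signals`` [channels x samples], ``/coords``
    [channels x 2], root attributes ``sampling_rate``, ``spatial_scale``,
    ``t_start``; ``/annotations`` and ``/history`` as JSON strings;
    optional ``/events/up``..., ``/waves/...`` and ``/flow/{u,v}`` groups.

``csv-bundle``
    A directory with ``signals.csv`` (wide, one column per channel),
    ``channels.csv`` (channel, x, y, active) and ``meta.yaml``.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import FlowField, GridRecording, TriggerSet, WaveSet

REQUIRED_META = ("sampling_rate", "spatial_scale")


class MissingMetadataError(KeyError):
    pass


def write_recording(rec: GridRecording, path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        _write_hdf5(rec, path)
    elif fmt == "csv-bundle":
        _write_csv_bundle(rec, path)
    else:
        raise ValueError(f"unknown format: {fmt!r} (use 'hdf5' or 'csv-bundle')")


def read_recording(path, format: str | None = None) -> GridRecording:
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "csv-bundle":
        return _read_csv_bundle(path)
    raise ValueError(f"unknown format: {fmt!r} (use 'hdf5' or 'csv-bundle')")


def _infer_format(path, format: str | None) -> str:
    if format is not None:
        return format
    p = Path(path)
    if p.suffix in {".h5", ".hdf5", ".nix"}:
        return "hdf5"
    return "csv-bundle"


# ---------------------------------------------------------------- hdf5

def _write_hdf5(rec: GridRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.signals)
        f.create_dataset("coords", data=rec.coords)
        f.create_dataset("active", data=rec.active.astype(np.uint8))
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["spatial_scale"] = rec.spatial_scale
        f.attrs["t_start"] = rec.t_start
        f.create_dataset("annotations", data=json.dumps(rec.annotations, default=str))
        f.create_dataset("history", data=json.dumps(rec.history, default=str))


def _read_hdf5(path) -> GridRecording:
    with h5py.File(path, "r") as f:
        for key in REQUIRED_META:
            if key not in f.attrs:
                raise MissingMetadataError(f"missing metadata: {key}")
        rec = GridRecording(
            signals=f["signals"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            spatial_scale=float(f.attrs["spatial_scale"]),
            coords=f["coords"][()],
            t_start=float(f.attrs.get("t_start", 0.0)),
            annotations=json.loads(f["annotations"][()]) if "annotations" in f else {},
            history=json.loads(f["history"][()]) if "history" in f else [],
            active=f["active"][()].astype(bool) if "active" in f else None,
        )
    return rec


def write_triggers(ts: TriggerSet, path) -> None:
    """Append trigger events to an existing HDF5 recording file (or create)."""
    with h5py.File(path, "a") as f:
        if "events" in f:
            del f["events"]
        g = f.create_group("events")
        up = g.create_group("up")
        for c, t in enumerate(ts.up):
            up.create_dataset(str(c), data=np.asarray(t))
        if ts.down is not None:
            dn = g.create_group("down")
            for c, t in enumerate(ts.down):
                dn.create_dataset(str(c), data=np.asarray(t))
        g.attrs["source"] = json.dumps(ts.source, default=str)


def read_triggers(path) -> TriggerSet:
    with h5py.File(path, "r") as f:
        g = f["events"]
        n = len(g["up"])
        up = [g["up"][str(c)][()] for c in range(n)]
        down = None
        if "down" in g:
            down = [g["down"][str(c)][()] for c in range(n)]
        source = json.loads(g.attrs.get("source", "{}"))
    return TriggerSet(up=up, down=down, source=source)


def write_waves(ws: WaveSet, path) -> None:
    with h5py.File(path, "a") as f:
        if "waves" in f:
            del f["waves"]
        g = f.create_group("waves")
        g.create_dataset("channels", data=ws.channels)
        g.create_dataset("times", data=ws.times)
        g.create_dataset("labels", data=ws.labels)
        g.attrs["params"] = json.dumps(ws.params, default=str)
        if ws.mode_labels is not None:
            g.attrs["mode_labels"] = json.dumps(
                {str(k): int(v) for k, v in ws.mode_labels.items()})


def read_waves(path) -> WaveSet:
    with h5py.File(path, "r") as f:
        g = f["waves"]
        modes = None
        if "mode_labels" in g.attrs:
            modes = {int(k): v for k, v in json.loads(g.attrs["mode_labels"]).items()}
        ws = WaveSet(
            channels=g["channels"][()],
            times=g["times"][()],
            labels=g["labels"][()],
            params=json.loads(g.attrs.get("params", "{}")),
            mode_labels=modes,
        )
    return ws


def write_flow(flow: FlowField, path) -> None:
    with h5py.File(path, "a") as f:
        if "flow" in f:
            del f["flow"]
        g = f.create_group("flow")
        g.create_dataset("u", data=flow.u)
        g.create_dataset("v", data=flow.v)
        g.attrs["params"] = json.dumps(flow.params, default=str)


def read_flow(path) -> FlowField:
    with h5py.File(path, "r") as f:
        g = f["flow"]
        flow = FlowField(u=g["u"][()], v=g["v"][()],
                         params=json.loads(g.attrs.get("params", "{}")))
    return flow


# ---------------------------------------------------------- csv bundle

def _write_csv_bundle(rec: GridRecording, path) -> None:
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    sig = pd.DataFrame(rec.signals.T, columns=[f"ch{c}" for c in range(rec.n_channels)])
    sig.insert(0, "time", rec.times)
    sig.to_csv(d / "signals.csv", index=False)
    pd.DataFrame({
        "channel": np.arange(rec.n_channels),
        "x": rec.coords[:, 0],
        "y": rec.coords[:, 1],
        "active": rec.active.astype(int),
    }).to_csv(d / "channels.csv", index=False)
    meta = {
        "sampling_rate": float(rec.sampling_rate),
        "spatial_scale": float(rec.spatial_scale),
        "t_start": float(rec.t_start),
        "annotations": _yaml_safe(rec.annotations),
        "history": _yaml_safe(rec.history),
    }
    with open(d / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def _read_csv_bundle(path) -> GridRecording:
    d = Path(path)
    with open(d / "meta.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    for key in REQUIRED_META:
        if key not in meta:
            raise MissingMetadataError(f"missing metadata: {key}")
    sig = pd.read_csv(d / "signals.csv")
    chan = pd.read_csv(d / "channels.csv")
    cols = [c for c in sig.columns if c != "time"]
    return GridRecording(
        signals=sig[cols].to_numpy().T,
        sampling_rate=float(meta["sampling_rate"]),
        spatial_scale=float(meta["spatial_scale"]),
        coords=chan[["x", "y"]].to_numpy(),
        t_start=float(meta.get("t_start", 0.0)),
        annotations=meta.get("annotations", {}) or {},
        history=meta.get("history", []) or [],
        active=chan["active"].to_numpy().astype(bool) if "active" in chan else None,
    )


def _yaml_safe(obj):
    """Coerce numpy scalars/arrays to plain Python for YAML output."""
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
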