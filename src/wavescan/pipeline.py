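"""Pipeline orchestration: config profiles, stage execution, QC plots.

Stages run in the configured order, each reading the previous stage's
artifact and writing its own (HDF5 for recordings/waves, CSV for the
final table) together with a JSON provenance sidecar (block sequence,
parameters, package version, elapsed time).  Rerunning with an unchanged
config reuses cached outputs whose timestamps are newer than both the
config file and the stage input.

Config profiles follow a hierarchical lookup: for profile
``data1_subject3|methodA`` each stage first tries
``config_data1_subject3|methodA.yaml``, then strips underscore
subcategories one at a time keeping the ``|variation`` suffix; only when
the bare ``config|methodA.yaml`` is absent is the variation dropped and
the stripping restarted, falling back to ``config.yaml``.  Because ``|``
is awkward in some shells, ``@`` is accepted as an equivalent separator
in file names (``config_data1@methodA.yaml``).
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import characterize as _char
from . import io as _io
from . import processing as _proc
from . import synthetic as _syn
from . import triggers as _trig
from . import waves as _wav
from .core import GridRecording, TriggerSet, WaveSet


# ------------------------------------------------------------ config profiles

def profile_candidates(profile: str) -> list[str]:
    """Ordered config-file names tried for a profile (without suffix)."""
    if "|" in profile:
        base, variation = profile.split("|", 1)
    else:
        base, variation = profile, None
    names = []
    def strip_chain(b: str) -> list[str]:
        parts = [b]
        while "_" in parts[-1]:
            parts.append(parts[-1].rsplit("_", 1)[0])
        return parts
    if variation is not None:
        for prefix in strip_chain(base):
            names.append(f"config_{prefix}|{variation}")
        names.append(f"config|{variation}")
    for prefix in strip_chain(base):
        names.append(f"config_{prefix}")
    names.append("config")
    return names


def resolve_config(profile: str, available: list[str] | Path) -> str:
    """Pick the config file for a profile from the available file names.

    ``available`` may be a directory (its ``*.yaml`` files are listed) or
    an explicit list of file names.  Raises FileNotFoundError when not
    even the default ``config.yaml`` is present.
    """
    if not profile:
        profile = ""
    if isinstance(available, (str, Path)):
        files = sorted(p.name for p in Path(available).glob("*.yaml"))
    else:
        files = list(available)
    fileset = set(files)
    for name in profile_candidates(profile):
        for candidate in (name + ".yaml", name.replace("|", "@") + ".yaml"):
            if candidate in fileset:
                return candidate
    raise FileNotFoundError(
        f"no config for profile {profile!r} and no default config.yaml "
        f"among {sorted(fileset)}")


# ------------------------------------------------------------ stages

def _stage_simulate(cfg: dict, _inputs, out_path: Path, seed: int):
    pattern = cfg.get("pattern", "planar")
    n_waves = int(cfg.get("n_waves", 5))
    period = float(cfg.get("period", 4.0))
    v0 = float(cfg.get("v0", 15.0))
    n_x = int(cfg.get("n_x", 20))
    n_y = int(cfg.get("n_y", 20))
    scale = float(cfg.get("spatial_scale", 0.05))
    rate = float(cfg.get("sampling_rate", 25.0))
    if pattern == "planar":
        gt = _syn.planar_wave_train(n_waves, period, v0,
                                    theta=float(cfg.get("theta", 0.0)))
    else:
        origin = cfg.get("origin", [n_x * scale / 2, n_y * scale / 2])
        gt = _syn.radial_wave_train(n_waves, period, v0, origin=tuple(origin))
    kernel = _syn.CalciumKernel(**cfg.get("kernel", {}))
    rec, gt = _syn.make_wave_recording(
        n_x, n_y, scale, rate, gt, kernel,
        noise_sd=float(cfg.get("noise_sd", 0.05)), seed=int(cfg.get("seed", seed)))
    _io.write_recording(rec, out_path)
    return rec


def _stage_process(cfg: dict, inputs, out_path: Path, seed: int):
    rec = inputs if isinstance(inputs, GridRecording) else _io.read_recording(inputs)
    blocks = [(b["name"], {k: v for k, v in b.items() if k != "name"})
              if isinstance(b, dict) else (b, {})
              for b in cfg.get("blocks", [])]
    rec = _proc.apply_blocks(rec, blocks)
    _io.write_recording(rec, out_path)
    return rec


def _stage_triggers(cfg: dict, inputs, out_path: Path, seed: int):
    rec = inputs if isinstance(inputs, GridRecording) else _io.read_recording(inputs)
    method = cfg.get("method", "hilbert")
    if method == "hilbert":
        ts = _trig.detect_hilbert_triggers(
            rec, phase_threshold=float(cfg.get("phase_threshold", -np.pi / 2)))
    elif method == "threshold":
        params = _trig.ThresholdParams(
            method=cfg.get("threshold_method", "bimodal_fit"),
            fixed_value=float(cfg.get("fixed_value", 0.0)),
            sigma_factor=float(cfg.get("sigma_factor", 3.0)),
            fallback_to_left_peak=bool(cfg.get("fallback_to_left_peak", False)))
        ts = _trig.detect_threshold_triggers(rec, params)
        if "min_up" in cfg or "min_down" in cfg:
            ts = _trig.filter_min_state_durations(
                ts, float(cfg.get("min_up", 0.0)), float(cfg.get("min_down", 0.0)))
    elif method == "minima":
        ts = _trig.detect_minima_triggers(rec, _trig.MinimaParams(
            window_len=float(cfg["window_len"]),
            min_peak_distance=float(cfg["min_peak_distance"]),
            rise_interval=float(cfg["rise_interval"]),
            peak_threshold=float(cfg.get("peak_threshold", 0.5))))
    else:
        raise ValueError(f"unknown trigger method {method!r}")
    _io.write_recording(rec, out_path)
    _io.write_triggers(ts, out_path)
    return (rec, ts)


def _stage_waves(cfg: dict, inputs, out_path: Path, seed: int):
    rec, ts = inputs
    if "time_space_ratio" in cfg:
        ratio = float(cfg["time_space_ratio"])
    else:
        ratio = _wav.compute_time_space_ratio(
            float(cfg.get("v0", 15.0)), rec.sampling_rate, rec.spatial_scale)
    ws = _wav.cluster_triggers_to_waves(ts, rec, _wav.WaveClusteringParams(
        time_space_ratio=ratio,
        neighbour_distance=float(cfg.get("neighbour_distance", 2.0)),
        min_samples_per_wave=int(cfg.get("min_samples_per_wave", 10))))
    ws = _wav.dedupe_channel_triggers(ws, policy=cfg.get("dedupe", "keep_earliest"))
    flow = None
    if cfg.get("flow", True):
        field = _wav.phase_field(rec)
        flow = _wav.compute_optical_flow(field, _wav.OpticalFlowParams(
            alpha=float(cfg.get("alpha", 1.5))))
    if cfg.get("modes"):
        ws = _wav.cluster_wave_modes(ws, int(cfg["modes"]), rec.n_channels,
                                     seed=seed)
    _io.write_recording(rec, out_path)
    _io.write_waves(ws, out_path)
    if flow is not None:
        _io.write_flow(flow, out_path)
    return (rec, ws, flow)


def _stage_characterize(cfg: dict, inputs, out_path: Path, seed: int):
    rec, ws, flow = inputs
    table = _char.emit_table(
        rec, ws, out_path, flow=flow,
        variant=cfg.get("variant", "wave_wise"),
        annotation_keys=cfg.get("annotations"),
        velocity_method=cfg.get("velocity_method", "central"),
        velocity_window=int(cfg.get("velocity_window", 5)))
    return table


def _load_recording(path):
    return _io.read_recording(path)


def _load_triggers(path):
    return (_io.read_recording(path), _io.read_triggers(path))


def _load_waves(path):
    import h5py
    with h5py.File(path, "r") as f:
        has_flow = "flow" in f
    flow = _io.read_flow(path) if has_flow else None
    return (_io.read_recording(path), _io.read_waves(path), flow)


def _load_table(path):
    import pandas as pd
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    from .core import CharacterizationTable
    return CharacterizationTable(pd.read_csv(path), meta.get("units", {}),
                                 meta.get("provenance", {}))


STAGES = {
    "simulate": (_stage_simulate, "recording.h5", _load_recording),
    "process": (_stage_process, "processed.h5", _load_recording),
    "triggers": (_stage_triggers, "triggers.h5", _load_triggers),
    "waves": (_stage_waves, "waves.h5", _load_waves),
    "characterize": (_stage_characterize, "table.csv", _load_table),
}


def run_pipeline(config: dict | str | Path, out_dir, profile: str | None = None,
                 config_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in order.

    ``config`` is the top-level configuration (dict or YAML path) with a
    ``stages`` list and optional ``global`` parameter map that overrides
    stage parameters (e.g., a shared ``seed`` or ``plot_format``).  When
    ``profile`` and ``config_dir`` are given, each stage's parameters are
    read from the profile-resolved per-stage config file
    (``<config_dir>/<stage>/config*.yaml``) before overrides apply.
    Returns the path of the final artifact.
    """
    config_mtime = None
    if not isinstance(config, dict):
        config_mtime = Path(config).stat().st_mtime
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_names = config.get("stages", ["simulate", "process", "triggers",
                                        "waves", "characterize"])
    global_cfg = dict(config.get("global", {}))
    seed = int(global_cfg.get("seed", 0))
    plot = bool(global_cfg.get("plots", False))
    plot_format = global_cfg.get("plot_format", "png")
    use_cache = bool(global_cfg.get("cache", True))
    inputs = config.get("input")
    result = inputs
    prev_mtime = config_mtime
    for stage in stage_names:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; available: {sorted(STAGES)}")
        func, artifact, loader = STAGES[stage]
        cfg = dict(config.get(stage, {}))
        if profile is not None and config_dir is not None:
            stage_dir = Path(config_dir) / stage
            if stage_dir.is_dir():
                chosen = resolve_config(profile, stage_dir)
                with open(stage_dir / chosen) as fh:
                    cfg = {**(yaml.safe_load(fh) or {}), **cfg}
        cfg.update({k: v for k, v in global_cfg.items()
                    if k not in ("seed", "plots", "plot_format", "cache")})
        out_path = out_dir / artifact
        fresh = (use_cache and out_path.exists()
                 and (prev_mtime is None or out_path.stat().st_mtime >= prev_mtime))
        t0 = time.time()
        if fresh:
            result = loader(out_path)
            cached = True
        else:
            cached = False
            try:
                result = func(cfg, result, out_path, seed)
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed with parameters {cfg}: {exc}") from exc
        log = {"stage": stage, "params": cfg, "seed": seed, "cached": cached,
               "version": __version__, "elapsed_s": round(time.time() - t0, 3),
               "artifact": str(out_path)}
        with open(out_dir / f"{stage}.log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        if plot and not cached:
            qc_plots(stage, result, out_dir, fmt=plot_format)
        prev_mtime = out_path.stat().st_mtime if out_path.exists() else None
    return out_dir / STAGES[stage_names[-1]][1]


# ------------------------------------------------------------ QC plots

def qc_plots(stage: str, result, out_dir, fmt: str = "png") -> list[Path]:
    """Best-effort diagnostic plots per stage; failures warn, never raise."""
    out_dir = Path(out_dir)
    paths: list[Path] = []
    try:
        import matplotlib
        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt
        if stage in ("simulate", "process"):
            rec = result
            fig, ax = plt.subplots(figsize=(8, 3))
            for c in range(0, rec.n_channels, max(1, rec.n_channels // 8)):
                ax.plot(rec.times, rec.signals[c], lw=0.6)
            ax.set(xlabel="time (s)", ylabel="signal", title=f"{stage}: traces")
        elif stage == "triggers":
            rec, ts = result
            fig, ax = plt.subplots(figsize=(8, 3))
            c0 = next((c for c in range(rec.n_channels) if len(ts.up[c])), 0)
            ax.plot(rec.times, rec.signals[c0], lw=0.8)
            for t in ts.up[c0]:
                ax.axvline(t, color="k", lw=0.6)
            ax.set(xlabel="time (s)", title=f"channel {c0}: signal with up triggers")
        elif stage == "waves":
            rec, ws, flow = result
            fig, ax = plt.subplots(figsize=(4, 4))
            if ws.n_waves:
                from .characterize import build_delay_map
                dm = build_delay_map(ws, int(ws.wave_ids[0]), rec)
                im = ax.imshow(dm.T, origin="lower", cmap="viridis")
                fig.colorbar(im, ax=ax, label="delay (s)")
                ax.set(title=f"wave {int(ws.wave_ids[0])} delay map")
            else:
                ax.text(0.5, 0.5, "no waves detected", ha="center")
                warnings.warn("wave stage produced an empty wave set",
                              RuntimeWarning, stacklevel=2)
        else:
            table = result
            fig, ax = plt.subplots(figsize=(5, 3))
            if len(table) and "velocity" in table.frame:
                table.frame.velocity.plot.hist(ax=ax, bins=20)
            ax.set(title="wave velocities (mm/s)")
        path = out_dir / f"{stage}.qc.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    except Exception as exc:  # plotting must never fail the run
        warnings.warn(f"QC plot for stage {stage!r} failed: {exc}",
                      RuntimeWarning, stacklevel=2)
    return paths
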