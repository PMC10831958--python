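"""Wave-wise and channel-wise measures of detected waves.

The central quantity is the delay map T(x, y) of a wave -- when the wave
reached each site, relative to its earliest trigger.  The channel-wise
velocity is the inverse gradient magnitude of T,

    v(x, y) = 1 / sqrt((dT/dx)^2 + (dT/dy)^2),

with derivatives in s/mm so v comes out in mm/s.  Directions are taken
from the optical flow vectors at the trigger events, and the planarity
of a wave is the resultant length of its direction vectors,

    P = ||sum v_i|| / sum ||v_i||,

which is 1 for perfectly aligned (planar) propagation and near 0 for
incoherent or symmetric patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import CharacterizationTable, FlowField, GridRecording, WaveSet
from .waves import wave_directions_from_flow

#: Channel-wise velocities above this (mm/s) are flagged as implausible
#: and excluded from reported distributions and aggregates.
VELOCITY_CAP = 120.0


@dataclass
class WaveDelayMap:
    """Per-site arrival delay of one wave (seconds since wave onset).

    NaN marks sites the wave did not reach.  The minimum over valid
    sites is 0 by construction.
    """

    T: np.ndarray  # (n_y, n_x)
    spatial_scale: float
    wave_id: int


def build_delay_map(ws: WaveSet, wave_id: int, rec: GridRecording) -> WaveDelayMap:
    """Delay map of one wave; requires one trigger per channel (dedupe
    first) and at least 3 sites so a gradient is defined."""
    chans, times = ws.wave(wave_id)
    if len(np.unique(chans)) != len(chans):
        raise ValueError(
            f"wave {wave_id} has channels with multiple triggers; "
            "apply dedupe_channel_triggers first")
    if len(chans) < 3:
        raise ValueError(f"wave {wave_id} spans fewer than 3 sites")
    n_y, n_x = rec.grid_shape
    T = np.full((n_y, n_x), np.nan)
    T[rec.coords[chans, 1], rec.coords[chans, 0]] = times - times.min()
    return WaveDelayMap(T=T, spatial_scale=rec.spatial_scale, wave_id=int(wave_id))


def _nan_gradient_1d(T: np.ndarray, axis: int, spacing: float) -> np.ndarray:
    """Finite-difference gradient: central where both neighbours are
    valid, one-sided at boundaries and NaN edges, NaN otherwise."""
    plus = np.roll(T, -1, axis=axis)
    minus = np.roll(T, 1, axis=axis)
    edge_last = [slice(None)] * T.ndim
    edge_last[axis] = -1
    edge_first = [slice(None)] * T.ndim
    edge_first[axis] = 0
    plus[tuple(edge_last)] = np.nan
    minus[tuple(edge_first)] = np.nan
    ok_p = np.isfinite(plus)
    ok_m = np.isfinite(minus)
    out = np.full(T.shape, np.nan)
    both = ok_p & ok_m
    out[both] = (plus[both] - minus[both]) / (2 * spacing)
    fwd = ok_p & ~ok_m & np.isfinite(T)
    out[fwd] = (plus[fwd] - T[fwd]) / spacing
    bwd = ok_m & ~ok_p & np.isfinite(T)
    out[bwd] = (T[bwd] - minus[bwd]) / spacing
    return out


def _plane_fit_gradient(T: np.ndarray, spacing: float, window: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Local least-squares plane fit of T in a window around each site.

    Robust alternative to finite differences when trigger times carry
    jitter comparable to the inter-site delays.  Returns (dT/dx, dT/dy)
    in s/mm.
    """
    half = window // 2
    n_y, n_x = T.shape
    gx = np.full_like(T, np.nan)
    gy = np.full_like(T, np.nan)
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    for y in range(n_y):
        for x in range(n_x):
            if not np.isfinite(T[y, x]):
                continue
            sl = (slice(max(0, y - half), y + half + 1),
                  slice(max(0, x - half), x + half + 1))
            tw = T[sl]
            valid = np.isfinite(tw)
            if valid.sum() < 6:
                continue
            X = np.column_stack([
                np.ones(valid.sum()),
                xx[sl][valid] * spacing,
                yy[sl][valid] * spacing,
            ])
            coef, *_ = np.linalg.lstsq(X, tw[valid], rcond=None)
            gx[y, x] = coef[1]
            gy[y, x] = coef[2]
    return gx, gy


def channel_velocity(dm: WaveDelayMap, method: str = "central",
                     window: int = 5) -> np.ndarray:
    """Channel-wise wave speed v = 1/||grad T|| in mm/s.

    ``method='central'`` uses central finite differences (exact for a
    linear delay map); ``method='plane_fit'`` fits a local plane in a
    ``window x window`` neighbourhood, which suppresses trigger-time
    jitter on noisy data.  Sites with a vanishing gradient are NaN
    (undefined, not infinite).
    """
    scale = dm.spatial_scale
    if method == "central":
        gx = _nan_gradient_1d(dm.T, axis=1, spacing=scale)
        gy = _nan_gradient_1d(dm.T, axis=0, spacing=scale)
    elif method == "plane_fit":
        gx, gy = _plane_fit_gradient(dm.T, scale, window)
    else:
        raise ValueError(f"unknown gradient method {method!r}")
    gnorm = np.hypot(gx, gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = 1.0 / gnorm
    v[gnorm == 0] = np.nan
    return v


def cap_velocities(values: np.ndarray, cap: float = VELOCITY_CAP
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Split velocities into (reported, flagged_mask).

    Values above the cap arise from near-identical delays at distant
    sites and are excluded from reported distributions; the mask lets
    callers keep the raw values alongside a flag.
    """
    values = np.asarray(values, dtype=float)
    flagged = values > cap
    return values[~flagged & np.isfinite(values)], flagged


def planarity(vectors: np.ndarray) -> float:
    """Alignment of a wave's direction vectors on a 0..1 scale:
    P = ||sum v_i|| / sum ||v_i||."""
    vectors = np.asarray(vectors, dtype=float).reshape(-1, 2)
    norms = np.linalg.norm(vectors, axis=1)
    total = norms.sum()
    if total == 0:
        raise ValueError("all direction vectors are zero")
    # the triangle inequality bounds P by 1; clamp float round-off
    return float(min(np.linalg.norm(vectors.sum(axis=0)) / total, 1.0))


def interwave_intervals(ws: WaveSet) -> dict[int, np.ndarray]:
    """Per-channel delays between consecutive wave passages (seconds)."""
    per_channel: dict[int, list[float]] = {}
    for w in ws.wave_ids:
        chans, times = ws.wave(w)
        for c, t in zip(chans, times):
            per_channel.setdefault(int(c), []).append(t)
    return {c: np.diff(np.sort(np.asarray(ts)))
            for c, ts in per_channel.items()}


def circular_mean_direction(vectors: np.ndarray) -> float:
    """Angle of the resultant vector; NaN when the resultant is
    negligible (opposing directions cancel)."""
    vectors = np.asarray(vectors, dtype=float).reshape(-1, 2)
    s = vectors.sum(axis=0)
    norms = np.linalg.norm(vectors, axis=1).sum()
    if norms == 0 or np.linalg.norm(s) < 1e-9 * norms:
        return float("nan")
    return float(np.arctan2(s[1], s[0]))


def wave_wise_aggregate(channel_velocities: np.ndarray,
                        direction_vectors: np.ndarray,
                        cap: float = VELOCITY_CAP) -> dict:
    """Collapse channel rows of one wave into a single wave row.

    Velocity: mean of the capped channel values; direction: circular
    mean of the flow vectors (NaN + flag when the directions cancel).
    """
    velocities = np.asarray(channel_velocities, dtype=float)
    if velocities.size == 0 and np.asarray(direction_vectors).size == 0:
        raise ValueError("empty wave")
    kept, flagged = cap_velocities(velocities, cap)
    direction = circular_mean_direction(direction_vectors)
    return {
        "velocity": float(np.mean(kept)) if kept.size else float("nan"),
        "direction": direction,
        "direction_undefined": bool(np.isnan(direction)),
        "n_channels": int(np.isfinite(velocities).sum()),
        "n_capped": int(flagged.sum()),
    }


def hedges_effect_size(a: np.ndarray, b: np.ndarray) -> float:
    """Hedges' effect size |mean(A)-mean(B)| / pooled sd with the
    (N-1)-weighted pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per group")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    return float(abs(a.mean() - b.mean()) / pooled)


def kde_summary(values: np.ndarray, measure_kind: str = "generic",
                grid: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of a measure distribution.

    Bandwidth follows Scott's rule except for interwave intervals, where
    the kernel size is fixed at 0.2 times the sample standard deviation.
    Returns (grid, density).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(np.unique(values)) < 2:
        raise ValueError("need at least 2 distinct values for a KDE")
    bw = 0.2 if measure_kind == "interwave_interval" else "scott"
    kde = scipy.stats.gaussian_kde(values, bw_method=bw)
    if grid is None:
        lo, hi = values.min(), values.max()
        pad = 4 * values.std()
        grid = np.linspace(lo - pad, hi + pad, 512)
    return grid, kde(grid)


# ------------------------------------------------------------ tables

def characterize_waves(rec: GridRecording, ws: WaveSet, flow: FlowField | None = None,
                 variant: str = "wave_wise",
                 annotation_keys: list[str] | None = None,
                 velocity_method: str = "central", velocity_window: int = 5,
                 cap: float = VELOCITY_CAP) -> CharacterizationTable:
    """Compute the measure table for all waves.

    ``variant='wave_wise'`` emits one row per wave (velocity, direction,
    planarity, mode, counts); ``variant='channel_wise'`` one row per
    (wave, channel) with the local velocity and flow direction.
    Requested recording annotations are copied into every row.
    """
    if variant not in ("wave_wise", "channel_wise"):
        raise ValueError(f"unknown variant {variant!r}")
    annotation_keys = annotation_keys or []
    for key in annotation_keys:
        if key not in rec.annotations:
            raise KeyError(f"unknown annotation key {key!r}; "
                           f"available: {sorted(rec.annotations)}")
    directions = {}
    n_skipped = 0
    if flow is not None:
        directions, n_skipped = wave_directions_from_flow(ws, flow, rec)
    iwi = interwave_intervals(ws)
    rows = []
    for w in ws.wave_ids:
        chans, times = ws.wave(w)
        dm = build_delay_map(ws, w, rec)
        vmap = channel_velocity(dm, method=velocity_method, window=velocity_window)
        vecs = directions.get(int(w), np.empty((0, 2)))
        mode = ws.mode_labels.get(int(w)) if ws.mode_labels else None
        if variant == "wave_wise":
            vel = vmap[rec.coords[chans, 1], rec.coords[chans, 0]]
            agg = wave_wise_aggregate(vel, vecs, cap=cap)
            try:
                p = planarity(vecs) if len(vecs) else float("nan")
            except ValueError:
                p = float("nan")
            row = {"wave_id": int(w), "onset": float(times.min()),
                   "n_triggers": len(chans), "velocity": agg["velocity"],
                   "direction": agg["direction"], "planarity": p,
                   "n_capped": agg["n_capped"], "mode": mode}
            for key in annotation_keys:
                row[key] = rec.annotations[key]
            rows.append(row)
        else:
            for i, (c, t) in enumerate(zip(chans, times)):
                x, y = rec.coords[c]
                vel = vmap[y, x]
                vec = vecs[i] if i < len(vecs) else (np.nan, np.nan)
                row = {"wave_id": int(w), "channel": int(c), "x": int(x),
                       "y": int(y), "trigger_time": float(t),
                       "velocity": float(vel),
                       "velocity_capped": bool(np.isfinite(vel) and vel > cap),
                       "direction": float(np.arctan2(vec[1], vec[0]))
                       if np.isfinite(vec).all() else float("nan"),
                       "mode": mode}
                for key in annotation_keys:
                    row[key] = rec.annotations[key]
                rows.append(row)
    frame = pd.DataFrame(rows)
    if variant == "channel_wise" and len(frame):
        # interwave interval of the passage ending at each trigger
        frame["interwave_interval"] = np.nan
        for c, intervals in iwi.items():
            sel = frame.channel == c
            t_sorted = np.sort(frame.loc[sel, "trigger_time"].to_numpy())
            lookup = dict(zip(t_sorted[1:], intervals))
            frame.loc[sel, "interwave_interval"] = [
                lookup.get(t, np.nan) for t in frame.loc[sel, "trigger_time"]]
    units = {"onset": "s", "trigger_time": "s", "velocity": "mm/s",
             "direction": "rad", "planarity": "", "interwave_interval": "s"}
    prov = {"variant": variant, "velocity_method": velocity_method,
            "velocity_cap_mm_per_s": cap, "wave_params": ws.params,
            "flow_params": flow.params if flow is not None else None,
            "n_skipped_directions": n_skipped,
            "history": rec.history}
    return CharacterizationTable(frame, units={k: v for k, v in units.items()
                                               if k in frame.columns}, provenance=prov)


def emit_table(rec: GridRecording, ws: WaveSet, path, flow: FlowField | None = None,
               variant: str = "wave_wise", annotation_keys: list[str] | None = None,
               **kwargs) -> CharacterizationTable:
    """Characterize and write the table as CSV (+ JSON units sidecar)."""
    table = characterize_waves(rec, ws, flow=flow, variant=variant,
                         annotation_keys=annotation_keys, **kwargs)
    table.to_csv(path)
    return table
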