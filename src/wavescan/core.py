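"""Shared data containers for grid recordings and derived wave objects.

The analysis operates on recordings from a rectangular grid of sensors
(electrodes or imaging pixels).  Every container carries enough metadata
(sampling rate in Hz, inter-site spacing in mm, integer site coordinates)
to make downstream measures expressible in physical units: times in
seconds, distances in mm, velocities in mm/s.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

#: Label used for triggers that belong to no wave (density-clustering noise).
NOISE = -1


@dataclass
class GridRecording:
    """A multichannel time series recorded on a rectangular integer grid.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)``.  Units are whatever the
        acquisition produced (µV, ΔF/F, dimensionless after z-scoring);
        they are tracked in ``annotations['units']`` when known.
    sampling_rate
        Sampling rate in Hz, strictly positive.
    spatial_scale
        Distance between neighbouring grid sites in mm, strictly positive.
    coords
        Integer array ``(n_channels, 2)`` of (x, y) grid positions.
        x increases rightward, y upward; the grid spans
        ``0 <= x < n_x`` and ``0 <= y < n_y``.  Sites without a channel are
        simply absent from ``coords`` (empty sites are allowed).
    t_start
        Time of the first sample in seconds.
    annotations
        Free-form metadata (anesthetic, dose, dataset id, units, ...).
    history
        Append-only list of processing steps, each a dict with at least
        ``name`` and ``params``.
    active
        Optional boolean mask per channel; channels switched off by a
        region-of-interest selection stay in place but are skipped by
        the detectors.
    """

    signals: np.ndarray
    sampling_rate: float
    spatial_scale: float
    coords: np.ndarray
    t_start: float = 0.0
    annotations: dict = field(default_factory=dict)
    history: list = field(default_factory=list)
    active: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.active is None:
            self.active = np.ones(self.signals.shape[0], dtype=bool)
        else:
            self.active = np.asarray(self.active, dtype=bool)

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def t_stop(self) -> float:
        return self.t_start + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.sampling_rate

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_y, n_x) of the bounding rectangular grid."""
        if self.coords.size == 0:
            return (0, 0)
        return (int(self.coords[:, 1].max()) + 1, int(self.coords[:, 0].max()) + 1)

    def channel_grid(self) -> np.ndarray:
        """Map grid sites to channel indices; -1 marks empty sites."""
        n_y, n_x = self.grid_shape
        grid = np.full((n_y, n_x), -1, dtype=int)
        grid[self.coords[:, 1], self.coords[:, 0]] = np.arange(self.n_channels)
        return grid

    def frames(self) -> np.ndarray:
        """Signals rearranged to ``(n_samples, n_y, n_x)``, NaN at empty
        or inactive sites."""
        n_y, n_x = self.grid_shape
        out = np.full((self.n_samples, n_y, n_x), np.nan)
        act = self.active
        out[:, self.coords[act, 1], self.coords[act, 0]] = self.signals[act].T
        return out

    # -- bookkeeping ----------------------------------------------------
    def append_history(self, name: str, params: Mapping[str, Any]) -> None:
        """Record a processing step.  History is append-only by contract."""
        self.history.append({"name": name, "params": dict(params)})

    def copy(self, signals: np.ndarray | None = None) -> "GridRecording":
        """Deep-ish copy, optionally substituting the signal matrix."""
        return GridRecording(
            signals=self.signals.copy() if signals is None else np.asarray(signals, float),
            sampling_rate=self.sampling_rate,
            spatial_scale=self.spatial_scale,
            coords=self.coords.copy(),
            t_start=self.t_start,
            annotations=_copy.deepcopy(self.annotations),
            history=_copy.deepcopy(self.history),
            active=self.active.copy(),
        )


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str]

    def __bool__(self) -> bool:
        return self.passed


def check_input(rec: GridRecording) -> ValidationReport:
    """Validate a recording against the pipeline's input contract.

    Returns a pass/fail report listing every violated invariant; never
    raises and never mutates the recording.
    """
    violations: list[str] = []
    try:
        sig = np.asarray(rec.signals)
        coords = np.asarray(rec.coords)
    except Exception:  # pragma: no cover - defensive
        return ValidationReport(False, ["signals/coords are not array-like"])

    if sig.ndim != 2:
        violations.append("signals must be a 2D [n_channels x n_samples] matrix")
    if not np.isfinite(rec.sampling_rate) or rec.sampling_rate <= 0:
        violations.append("sampling_rate must be > 0")
    if not np.isfinite(rec.spatial_scale) or rec.spatial_scale <= 0:
        violations.append("spatial_scale must be > 0")
    if coords.ndim != 2 or coords.shape[1] != 2:
        violations.append("coords must be an [n_channels x 2] integer array")
    else:
        if sig.ndim == 2 and coords.shape[0] != sig.shape[0]:
            violations.append("coords and signals disagree on n_channels")
        if len(np.unique(coords, axis=0)) != len(coords):
            violations.append("coords not unique")
        if coords.size and coords.min() < 0:
            violations.append("coords must be non-negative grid indices")
    if sig.ndim == 2 and sig.shape[0]:
        all_nan = np.all(np.isnan(sig), axis=1)
        if np.any(all_nan & rec.active):
            bad = np.flatnonzero(all_nan & rec.active)
            violations.append(f"NaN-only active channels: {bad.tolist()}")
    return ValidationReport(not violations, violations)


@dataclass
class TriggerSet:
    """Per-channel sorted transition times (seconds).

    ``up`` holds one sorted array of upward (down->up) transition times per
    channel; ``down`` optionally holds the matching downward transitions.
    When both are present they alternate per channel.
    """

    up: list[np.ndarray]
    down: list[np.ndarray] | None = None
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = [np.asarray(t, dtype=float) for t in self.up]
        if self.down is not None:
            self.down = [np.asarray(t, dtype=float) for t in self.down]

    @property
    def n_channels(self) -> int:
        return len(self.up)

    @property
    def n_triggers(self) -> int:
        return int(sum(len(t) for t in self.up))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (channel_index, time) arrays, channel-major order."""
        chans = np.concatenate(
            [np.full(len(t), c, dtype=int) for c, t in enumerate(self.up)]
        ) if self.n_triggers else np.empty(0, dtype=int)
        times = np.concatenate(self.up) if self.n_triggers else np.empty(0)
        return chans, times

    def validate(self, rec: GridRecording | None = None) -> None:
        """Raise ValueError on a violated invariant."""
        for c, t in enumerate(self.up):
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"channel {c}: up times not strictly increasing")
            if rec is not None and len(t):
                if t[0] < rec.t_start - 1e-9 or t[-1] > rec.t_stop + 1e-9:
                    raise ValueError(f"channel {c}: trigger outside recording span")
        if self.down is not None:
            for c, (tu, td) in enumerate(zip(self.up, self.down)):
                merged = np.sort(np.concatenate([tu, td]))
                kinds = np.concatenate([np.zeros(len(tu)), np.ones(len(td))])
                kinds = kinds[np.argsort(np.concatenate([tu, td]), kind="stable")]
                if np.any(np.diff(kinds) == 0):
                    raise ValueError(f"channel {c}: up/down do not alternate")
                del merged


@dataclass
class WaveSet:
    """Assignment of triggers to waves.

    ``channels``/``times`` flatten all triggers; ``labels`` gives each a
    wave id (>= 0) or :data:`NOISE`.  Wave ids are ordered by the wave's
    earliest trigger time.
    """

    channels: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    params: dict = field(default_factory=dict)
    mode_labels: dict | None = None  # wave_id -> mode id

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def wave_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != NOISE]

    @property
    def n_waves(self) -> int:
        return len(self.wave_ids)

    def wave(self, wave_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(channels, times) of one wave, sorted by time."""
        m = self.labels == wave_id
        order = np.argsort(self.times[m], kind="stable")
        return self.channels[m][order], self.times[m][order]

    @property
    def waves(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        return {int(w): self.wave(w) for w in self.wave_ids}

    def onset(self, wave_id: int) -> float:
        """Wave onset = time of its earliest trigger."""
        return float(self.times[self.labels == wave_id].min())


@dataclass
class FlowField:
    """Per-frame, per-site 2D vector field in grid units per frame."""

    u: np.ndarray  # (n_frames, n_y, n_x)
    v: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.u.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.u.shape[1:]


class CharacterizationTable:
    """Thin wrapper pairing a measures DataFrame with per-column units.

    One row per wave (wave-wise variant) or per (wave, channel)
    (channel-wise variant).  ``to_csv`` writes the table plus a JSON
    sidecar with units and the full parameter provenance.
    """

    def __init__(self, frame, units: Mapping[str, str], provenance: Mapping | None = None):
        self.frame = frame
        self.units = dict(units)
        self.provenance = dict(provenance or {})

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"units": self.units, "provenance": self.provenance}, fh,
                      indent=2, default=_json_default)

    def __len__(self) -> int:
        return len(self.frame)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def full_grid_coords(n_x: int, n_y: int) -> np.ndarray:
    """All (x, y) positions of an n_x-by-n_y grid, row-major in y then x."""
    xs, ys = np.meshgrid(np.arange(n_x), np.arange(n_y))
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(int)
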