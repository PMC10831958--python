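"""Grouping triggers into waves and estimating propagation vectors.

Triggers are clustered in the three-dimensional space (x, y, scaled
time) with a density-based algorithm; the time axis is scaled by the
TIME_SPACE_RATIO so that a wave travelling at the reference velocity v0
appears isotropic.  Channel-wise propagation directions come from
Horn-Schunck optical flow computed on the analytic-signal phase, and
waves can additionally be grouped into modes by k-means on their trigger
delay matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal
from sklearn.cluster import DBSCAN, KMeans

from .core import NOISE, FlowField, GridRecording, TriggerSet, WaveSet


def compute_time_space_ratio(v0: float, sampling_rate: float,
                             spatial_scale: float) -> float:
    """Time-axis scaling (grid units per frame) for trigger clustering.

    A wave propagating at ``v0`` (mm/s) covers
    ``v0 / (sampling_rate * spatial_scale)`` grid units per frame; scaling
    the frame axis by this ratio makes the wavefront isotropic in the
    clustering space.
    """
    if v0 <= 0 or sampling_rate <= 0 or spatial_scale <= 0:
        raise ValueError("v0, sampling_rate and spatial_scale must all be > 0")
    return v0 / (sampling_rate * spatial_scale)


@dataclass
class WaveClusteringParams:
    """Density-clustering parameters.

    ``time_space_ratio`` can be given directly or derived via
    :func:`compute_time_space_ratio` from an expected velocity.
    ``neighbour_distance`` is the clustering epsilon in grid units;
    ``min_samples_per_wave`` the minimum cluster size.
    """

    time_space_ratio: float
    neighbour_distance: float = 2.0
    min_samples_per_wave: int = 10

    def __post_init__(self) -> None:
        if self.time_space_ratio <= 0 or self.neighbour_distance <= 0 \
                or self.min_samples_per_wave <= 0:
            raise ValueError("all clustering parameters must be > 0")

    @classmethod
    def calibrated(cls, v0: float, sampling_rate: float, spatial_scale: float,
                   trigger_jitter_sd: float = 0.006,
                   min_samples_per_wave: int = 10) -> "WaveClusteringParams":
        """Clustering parameters matched to the expected dynamics.

        The neighbourhood distance must cover both the spatial spacing of
        adjacent sites (up to 2*sqrt(2) grid units for next-nearest
        neighbours) and the trigger-time jitter of the detector, which in
        scaled units grows with the time-space ratio:
        ``sigma_scaled = jitter_sd * sampling_rate * ratio``.  The default
        jitter (6 ms) is the empirical detection error of the
        Hilbert-phase detector on band-passed signals with moderate
        noise; pass the jitter of your own detector/data when known.
        """
        ratio = compute_time_space_ratio(v0, sampling_rate, spatial_scale)
        sigma_scaled = trigger_jitter_sd * sampling_rate * ratio
        eps = max(4.0, float(np.hypot(2 * np.sqrt(2.0), 3 * sigma_scaled)))
        return cls(time_space_ratio=ratio, neighbour_distance=eps,
                   min_samples_per_wave=min_samples_per_wave)


def cluster_triggers_to_waves(ts: TriggerSet, rec: GridRecording,
                              params: WaveClusteringParams) -> WaveSet:
    """DBSCAN over triggers embedded at (x, y, frames * ratio).

    Noise points get the label -1; wave ids are renumbered in order of
    each wave's earliest trigger.
    """
    chans, times = ts.as_arrays()
    if len(times) == 0:
        raise ValueError("empty trigger set")
    xy = rec.coords[chans].astype(float)
    t_frames = (times - rec.t_start) * rec.sampling_rate
    pts = np.column_stack([xy, t_frames * params.time_space_ratio])
    db = DBSCAN(eps=params.neighbour_distance,
                min_samples=params.min_samples_per_wave).fit(pts)
    labels = db.labels_.copy()
    # renumber by first trigger time
    ids = [w for w in np.unique(labels) if w != NOISE]
    onsets = {w: times[labels == w].min() for w in ids}
    order = sorted(ids, key=lambda w: onsets[w])
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap.get(l, NOISE) for l in labels])
    return WaveSet(channels=chans, times=times, labels=labels, params={
        "time_space_ratio": params.time_space_ratio,
        "neighbour_distance": params.neighbour_distance,
        "min_samples_per_wave": params.min_samples_per_wave})


def dedupe_channel_triggers(ws: WaveSet, policy: str = "keep_earliest") -> WaveSet:
    """Ensure each channel contributes at most one trigger per wave.

    The wave delay map T(x, y) presumes a single arrival time per site;
    under ``keep_earliest`` the earliest trigger of a channel within a
    wave is kept and later duplicates are relabelled as noise.
    ``keep_all`` returns the set unchanged (delay-map construction will
    then refuse duplicated channels).
    """
    if policy == "keep_all":
        return ws
    if policy != "keep_earliest":
        raise ValueError(f"unknown policy {policy!r}")
    labels = ws.labels.copy()
    for w in ws.wave_ids:
        idx = np.flatnonzero(labels == w)
        order = idx[np.argsort(ws.times[idx], kind="stable")]
        seen: set[int] = set()
        for i in order:
            c = int(ws.channels[i])
            if c in seen:
                labels[i] = NOISE
            else:
                seen.add(c)
    out = WaveSet(channels=ws.channels, times=ws.times, labels=labels,
                  params=dict(ws.params), mode_labels=ws.mode_labels)
    out.params["dedupe_policy"] = policy
    return out


# ------------------------------------------------------------ phase field

def phase_field(rec: GridRecording) -> np.ndarray:
    """Analytic-signal phase arranged on the grid.

    Returns ``(n_frames, n_y, n_x)`` with NaN at empty or inactive sites.
    Input should be detrended and z-scored.
    """
    n_y, n_x = rec.grid_shape
    out = np.full((rec.n_samples, n_y, n_x), np.nan)
    for c in range(rec.n_channels):
        if not rec.active[c] or not np.isfinite(rec.signals[c]).all():
            continue
        phase = np.angle(scipy.signal.hilbert(rec.signals[c]))
        out[:, rec.coords[c, 1], rec.coords[c, 0]] = phase
    return out


def trigger_frame_indices(ts: TriggerSet | WaveSet, rec: GridRecording,
                          pad: int = 2) -> np.ndarray:
    """Frame indices covering all trigger times (each padded by ``pad``
    frames), for restricting the optical-flow computation."""
    if isinstance(ts, WaveSet):
        times = ts.times
    else:
        _, times = ts.as_arrays()
    frames = np.round((np.asarray(times) - rec.t_start) * rec.sampling_rate).astype(int)
    out = np.unique(np.concatenate([frames + d for d in range(-pad, pad + 1)]))
    return out[(out >= 0) & (out < rec.n_samples)]


# ------------------------------------------------------------ optical flow

@dataclass
class OpticalFlowParams:
    """Horn-Schunck settings.

    ``alpha`` weighs the smoothness constraint against brightness
    constancy (quadratic penalties); the spatial derivative uses a 3x3
    Scharr-weighted stencil.  Before differentiation the field is
    spatially smoothed with a Gaussian of ``phase_smooth_sigma`` sites
    (performed on the unit phasor for phase input, so the +-pi seam is
    respected); set it to 0 to differentiate the raw field.  After
    convergence the vector field is smoothed with a Gaussian kernel of
    ``smooth_sigma`` = (frames, sites, sites).
    """

    alpha: float = 1.5
    max_iterations: int = 500
    tolerance: float = 1e-6
    smooth_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase_smooth_sigma: float = 1.0
    source: str = "phase"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.tolerance <= 0:
            raise ValueError("alpha and tolerance must be > 0")


_SCHARR_SIDE = np.array([3.0, 10.0, 3.0]) / 16.0  # one column of the 3x3 Scharr filter

_AVG_KERNEL = np.array([[1 / 12, 1 / 6, 1 / 12],
                        [1 / 6, 0.0, 1 / 6],
                        [1 / 12, 1 / 6, 1 / 12]])


def _masked_side_mean(z: np.ndarray, valid: np.ndarray, axis: int,
                      side: int) -> tuple[np.ndarray, np.ndarray]:
    """Scharr-weighted mean of the neighbouring row/column on one side.

    Operates on the last two axes of ``z`` (frames broadcast through the
    first axis).  Returns (mean, has_any_valid_weight).
    """
    shifted = np.roll(z, -side, axis=axis)
    vshift = np.roll(valid, -side, axis=axis)
    if side == 1:
        edge = [slice(None)] * z.ndim
        edge[axis] = -1
        vshift = vshift.copy()
        vshift[tuple(edge)] = False
    else:
        edge = [slice(None)] * z.ndim
        edge[axis] = 0
        vshift = vshift.copy()
        vshift[tuple(edge)] = False
    other = 1 if axis == 2 else 2  # the perpendicular spatial axis
    w = _SCHARR_SIDE
    num = np.zeros_like(z)
    den = np.zeros(z.shape, dtype=float)
    for k, off in enumerate((-1, 0, 1)):
        zz = np.roll(shifted, -off, axis=other)
        vv = np.roll(vshift, -off, axis=other)
        if off != 0:
            e = [slice(None)] * z.ndim
            e[other] = -1 if off == 1 else 0
            vv = vv.copy()
            vv[tuple(e)] = False
        num = num + w[k] * np.where(vv, zz, 0.0)
        den = den + w[k] * vv
    ok = den > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    return mean, ok


def _phase_spatial_derivative(z: np.ndarray, valid: np.ndarray,
                              axis: int) -> np.ndarray:
    """Wrap-safe spatial derivative of a phase field.

    ``z = exp(i*phase)``; the derivative of the phase along ``axis``
    (2 = y, 3 = x ... here axes are (frame, y, x) so 1 = y, 2 = x) is
    recovered as Im(conj(z) * dz).  On a fully valid 3x3 neighbourhood
    this reduces to the normalized Scharr filter; at mask borders each
    side degrades to the valid-weighted column mean, and sites with an
    empty side give NaN.
    """
    plus, ok_p = _masked_side_mean(z, valid, axis=axis, side=1)
    minus, ok_m = _masked_side_mean(z, valid, axis=axis, side=-1)
    with np.errstate(invalid="ignore"):
        dz = (plus - minus) / 2.0
        deriv = np.imag(np.conj(z) * dz)
    deriv[~(ok_p & ok_m & valid)] = np.nan
    return deriv


_AVG_KERNEL_3D = _AVG_KERNEL[None, :, :]  # frames are independent


def _nan_gaussian_smooth(a: np.ndarray, sigma) -> np.ndarray:
    """Gaussian smoothing that renormalizes around NaN sites."""
    nanmask = np.isnan(a)
    filled = np.where(nanmask, 0.0, a)
    weights = (~nanmask).astype(float)
    sm = scipy.ndimage.gaussian_filter(filled, sigma=sigma, mode="nearest")
    wsm = scipy.ndimage.gaussian_filter(weights, sigma=sigma, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sm / wsm
    out[nanmask] = np.nan
    return out


def compute_optical_flow(field: np.ndarray,
                         params: OpticalFlowParams | None = None,
                         frame_indices: np.ndarray | None = None) -> FlowField:
    """Horn-Schunck optical flow of a (phase) field.

    ``field`` is ``(n_frames, n_y, n_x)``; when ``params.source`` is
    ``"phase"`` all differences are taken circularly (wrapped into
    (-pi, pi]), so adding 2*pi to the field leaves the flow unchanged.
    The flow for frame t describes the apparent motion between frames t
    and t+1 (the last frame repeats the previous flow).  Units: grid
    units per frame.

    ``frame_indices`` restricts the (independent) per-frame-pair
    iterations to the listed frames; the remaining frames are NaN.  Use
    :func:`trigger_frame_indices` when flow is only needed at the wave
    trigger events.
    """
    params = params or OpticalFlowParams()
    field = np.asarray(field, dtype=float)
    if field.ndim != 3 or field.shape[0] < 2:
        raise ValueError("need a (n_frames >= 2, n_y, n_x) field")
    n_frames = field.shape[0]
    subset = None
    if frame_indices is not None:
        subset = np.unique(np.clip(np.asarray(frame_indices, dtype=int),
                                   0, n_frames - 2))
    circular = params.source == "phase"
    if circular:
        z = np.exp(1j * field)
        valid = np.isfinite(field)
        if params.phase_smooth_sigma > 0:
            sig = (0.0, params.phase_smooth_sigma, params.phase_smooth_sigma)
            zs = (_nan_gaussian_smooth(np.where(valid, z.real, np.nan), sig)
                  + 1j * _nan_gaussian_smooth(np.where(valid, z.imag, np.nan), sig))
            mag = np.abs(zs)
            z = np.where(valid & (mag > 0), zs / np.where(mag > 0, mag, 1.0), z)
        # temporal derivative: wrapped phase difference between frames
        it = np.angle(z[1:] * np.conj(z[:-1]))
        it[~(valid[1:] & valid[:-1])] = np.nan
        ix0 = _phase_spatial_derivative(z, valid, axis=2)
        iy0 = _phase_spatial_derivative(z, valid, axis=1)
    else:
        valid = np.isfinite(field)
        if params.phase_smooth_sigma > 0:
            sig = (0.0, params.phase_smooth_sigma, params.phase_smooth_sigma)
            field = np.where(valid, _nan_gaussian_smooth(field, sig), np.nan)
        it = field[1:] - field[:-1]
        it[~(valid[1:] & valid[:-1])] = np.nan
        zf = np.where(valid, field, 0.0)
        plus_x, okpx = _masked_side_mean(zf, valid, axis=2, side=1)
        minus_x, okmx = _masked_side_mean(zf, valid, axis=2, side=-1)
        ix0 = (plus_x - minus_x) / 2.0
        ix0[~(okpx & okmx & valid)] = np.nan
        plus_y, okpy = _masked_side_mean(zf, valid, axis=1, side=1)
        minus_y, okmy = _masked_side_mean(zf, valid, axis=1, side=-1)
        iy0 = (plus_y - minus_y) / 2.0
        iy0[~(okpy & okmy & valid)] = np.nan
    # average the spatial derivatives of the two frames of each pair
    ix = 0.5 * (ix0[:-1] + ix0[1:])
    iy = 0.5 * (iy0[:-1] + iy0[1:])
    if subset is not None:
        ix, iy, it = ix[subset], iy[subset], it[subset]
    ok = np.isfinite(ix) & np.isfinite(iy) & np.isfinite(it)
    okf = ok.astype(float)
    ixf = np.where(ok, ix, 0.0)
    iyf = np.where(ok, iy, 0.0)
    itf = np.where(ok, it, 0.0)
    alpha2 = params.alpha ** 2
    denom = alpha2 + ixf ** 2 + iyf ** 2
    # neighbour-average normalization is fixed across iterations
    navg_den = scipy.ndimage.correlate(okf, _AVG_KERNEL_3D, mode="constant")
    navg_den[navg_den == 0] = np.inf
    u = np.zeros_like(ixf)
    v = np.zeros_like(ixf)
    converged = False
    for _ in range(params.max_iterations):
        u_avg = scipy.ndimage.correlate(u * okf, _AVG_KERNEL_3D,
                                        mode="constant") / navg_den
        v_avg = scipy.ndimage.correlate(v * okf, _AVG_KERNEL_3D,
                                        mode="constant") / navg_den
        update = (ixf * u_avg + iyf * v_avg + itf) / denom
        u_new = u_avg - ixf * update
        v_new = v_avg - iyf * update
        delta = np.mean((u_new - u) ** 2 + (v_new - v) ** 2, axis=(1, 2))
        u, v = u_new, v_new
        if np.max(delta) < params.tolerance:
            converged = True
            break
    u[~ok] = np.nan
    v[~ok] = np.nan
    sigma = params.smooth_sigma
    if subset is not None:
        sigma = (0.0, *sigma[1:])  # frames are non-contiguous: spatial only
    u = _nan_gaussian_smooth(u, sigma)
    v = _nan_gaussian_smooth(v, sigma)
    if subset is not None:
        uf = np.full((n_frames, *field.shape[1:]), np.nan)
        vf = np.full((n_frames, *field.shape[1:]), np.nan)
        uf[subset] = u
        vf[subset] = v
        u, v = uf, vf
    else:
        # pad to the source frame count: the last frame repeats the
        # final pair's flow
        u = np.concatenate([u, u[-1:]], axis=0)
        v = np.concatenate([v, v[-1:]], axis=0)
    pinfo = {"alpha": params.alpha, "max_iterations": params.max_iterations,
             "tolerance": params.tolerance, "smooth_sigma": list(params.smooth_sigma),
             "source": params.source, "derivative_filter": "scharr3x3",
             "phase_smooth_sigma": params.phase_smooth_sigma,
             "converged": bool(converged),
             "frame_subset": subset.tolist() if subset is not None else None}
    if not converged:
        warnings.warn("optical flow did not converge within max_iterations",
                      RuntimeWarning, stacklevel=2)
    assert u.shape[0] == n_frames
    return FlowField(u=u, v=v, params=pinfo)


def wave_directions_from_flow(ws: WaveSet, flow: FlowField, rec: GridRecording
                              ) -> tuple[dict[int, np.ndarray], int]:
    """Per-trigger direction vectors from the flow field.

    For every trigger the (u, v) vector at its site and nearest frame is
    taken.  Returns ``(vectors_by_wave, n_skipped)`` where each entry is
    an ``(n, 2)`` array; triggers at masked sites or with undefined
    (NaN/zero) flow are skipped and counted.
    """
    n_skipped = 0
    out: dict[int, np.ndarray] = {}
    n_frames = flow.n_frames
    for w in ws.wave_ids:
        chans, times = ws.wave(w)
        vecs = []
        for c, t in zip(chans, times):
            frame = int(round((t - rec.t_start) * rec.sampling_rate))
            frame = min(max(frame, 0), n_frames - 1)
            x, y = rec.coords[c]
            uu = flow.u[frame, y, x]
            vv = flow.v[frame, y, x]
            if not (np.isfinite(uu) and np.isfinite(vv)) or (uu == 0 and vv == 0):
                n_skipped += 1
                continue
            vecs.append((uu, vv))
        out[int(w)] = np.asarray(vecs).reshape(-1, 2)
    return out, n_skipped


# ------------------------------------------------------------ wave modes

def trigger_delay_matrix(ws: WaveSet, n_channels: int,
                         imputation: str = "max") -> np.ndarray:
    """[n_waves x n_channels] matrix of trigger delays since wave onset.

    Channels a wave never reached are imputed with the wave's maximum
    delay ("late") by default, or the wave's mean delay with
    ``imputation='mean'``.
    """
    ids = ws.wave_ids
    mat = np.full((len(ids), n_channels), np.nan)
    for i, w in enumerate(ids):
        chans, times = ws.wave(w)
        onset = times.min()
        for c, t in zip(chans, times):
            # keep the earliest if a channel appears twice
            if np.isnan(mat[i, c]):
                mat[i, c] = t - onset
        fill = np.nanmax(mat[i]) if imputation == "max" else np.nanmean(mat[i])
        mat[i, np.isnan(mat[i])] = fill
    return mat


def cluster_wave_modes(ws: WaveSet, n_modes: int, n_channels: int,
                       seed: int = 0, imputation: str = "max") -> WaveSet:
    """Group waves into modes by k-means on the trigger delay matrix.

    Mode ids are ordered by cluster size (largest first).  Returns a new
    WaveSet with ``mode_labels`` filled in; ``params`` additionally
    records the between-cluster separation (k-means inertia).
    """
    ids = ws.wave_ids
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes > len(ids):
        raise ValueError(f"n_modes ({n_modes}) exceeds the number of waves ({len(ids)})")
    mat = trigger_delay_matrix(ws, n_channels, imputation=imputation)
    km = KMeans(n_clusters=n_modes, n_init=10, random_state=seed).fit(mat)
    sizes = np.bincount(km.labels_, minlength=n_modes)
    order = np.argsort(-sizes, kind="stable")
    remap = {int(old): int(new) for new, old in enumerate(order)}
    mode_labels = {int(w): remap[int(l)] for w, l in zip(ids, km.labels_)}
    out = WaveSet(channels=ws.channels, times=ws.times, labels=ws.labels,
                  params=dict(ws.params), mode_labels=mode_labels)
    out.params["mode_clustering"] = {
        "n_modes": n_modes, "seed": seed, "imputation": imputation,
        "inertia": float(km.inertia_)}
    return out
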