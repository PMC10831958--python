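"""Signal-conditioning blocks.

Any ordered combination of these blocks can be applied ("choose any"):
detrending, zero-phase band-pass filtering, z-scoring, background
subtraction, region-of-interest selection, spatial downsampling, and
logMUA estimation.  Each block returns a new recording and appends one
record with its full parameter set to the processing history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import GridRecording


def detrend(rec: GridRecording, order: int = 1) -> GridRecording:
    """Remove the per-channel mean (order 0) or best-fit line (order 1)."""
    if order not in (0, 1):
        raise ValueError("order must be 0 (mean) or 1 (linear)")
    kind = "constant" if order == 0 else "linear"
    out = rec.copy(signals=scipy.signal.detrend(rec.signals, axis=1, type=kind))
    out.append_history("detrend", {"order": order})
    return out


def band_pass_filter(rec: GridRecording, f_low: float, f_high: float,
                     order: int = 2) -> GridRecording:
    """Zero-phase Butterworth band-pass (forward-backward, per channel)."""
    nyq = rec.sampling_rate / 2
    if not (0 < f_low < f_high < nyq):
        raise ValueError(f"invalid band ({f_low}, {f_high}) for Nyquist {nyq} Hz")
    sos = scipy.signal.butter(order, [f_low, f_high], btype="band",
                              fs=rec.sampling_rate, output="sos")
    out = rec.copy(signals=scipy.signal.sosfiltfilt(sos, rec.signals, axis=1))
    out.append_history("band_pass_filter",
                       {"f_low": f_low, "f_high": f_high, "order": order})
    return out


def zscore(rec: GridRecording) -> GridRecording:
    """Per-channel (x - mean) / sd.  Zero-variance channels become NaN
    with a warning rather than raising."""
    mean = rec.signals.mean(axis=1, keepdims=True)
    sd = rec.signals.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance channel(s) set to NaN",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (rec.signals - mean) / sd
    z[flat] = np.nan
    out = rec.copy(signals=z)
    out.annotations["units"] = "z-score"
    out.append_history("zscore", {"zero_variance_channels": int(flat.sum())})
    return out


def subtract_background(rec: GridRecording, mode: str = "temporal_mean",
                        frame: np.ndarray | None = None) -> GridRecording:
    """Remove a per-site background: either each channel's temporal mean
    or a user-provided frame indexed by the channel's grid position."""
    if mode == "temporal_mean":
        background = rec.signals.mean(axis=1)
    elif mode == "provided_frame":
        if frame is None:
            raise ValueError("mode='provided_frame' requires a frame")
        frame = np.asarray(frame, dtype=float)
        if frame.shape != rec.grid_shape:
            raise ValueError(
                f"frame shape {frame.shape} does not match grid {rec.grid_shape}")
        background = frame[rec.coords[:, 1], rec.coords[:, 0]]
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    out = rec.copy(signals=rec.signals - background[:, None])
    out.append_history("subtract_background", {"mode": mode})
    return out


def roi_selection(rec: GridRecording, mask: np.ndarray) -> GridRecording:
    """Restrict analysis to the grid sites where ``mask`` is True.

    Channels outside the region of interest are marked inactive but not
    renumbered, so coordinates stay valid for all later stages.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rec.grid_shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {rec.grid_shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")
    out = rec.copy()
    out.active = out.active & mask[rec.coords[:, 1], rec.coords[:, 0]]
    out.append_history("roi_selection", {"n_active": int(out.active.sum())})
    return out


def spatial_downsample(rec: GridRecording, factor: int) -> GridRecording:
    """Average non-overlapping factor-by-factor blocks of sites.

    Mimics recording the same activity with coarser sensors: the new
    inter-site spacing is ``factor * spatial_scale`` and the grid shrinks
    to ``ceil(n / factor)`` per axis.  Inactive/empty sites are ignored
    in each block mean; blocks with no active site become inactive.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    n_y, n_x = rec.grid_shape
    if factor > max(n_x, n_y):
        raise ValueError(f"factor {factor} exceeds both grid dimensions {n_x}x{n_y}")
    if factor == 1:
        out = rec.copy()
        out.append_history("spatial_downsample", {"factor": 1})
        return out
    new_nx = -(-n_x // factor)
    new_ny = -(-n_y // factor)
    block_x = rec.coords[:, 0] // factor
    block_y = rec.coords[:, 1] // factor
    signals = np.zeros((new_nx * new_ny, rec.n_samples))
    counts = np.zeros(new_nx * new_ny, dtype=int)
    flat = block_y * new_nx + block_x
    for c in range(rec.n_channels):
        if rec.active[c]:
            signals[flat[c]] += rec.signals[c]
            counts[flat[c]] += 1
    occupied = counts > 0
    signals[occupied] /= counts[occupied, None]
    xs, ys = np.meshgrid(np.arange(new_nx), np.arange(new_ny))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    out = GridRecording(
        signals=signals, sampling_rate=rec.sampling_rate,
        spatial_scale=rec.spatial_scale * factor, coords=coords,
        t_start=rec.t_start, annotations=dict(rec.annotations),
        history=list(rec.history), active=occupied,
    )
    out.append_history("spatial_downsample", {"factor": factor})
    return out


@dataclass
class LogMuaParams:
    """Parameters of the spectral multi-unit-activity estimate.

    ``band`` is the high-frequency range whose relative power tracks
    population firing (default 200-1500 Hz); ``window_size`` the moving
    window in seconds and ``mua_rate`` the output sampling rate in Hz.
    The window must span at least one period of the band's low edge
    (``window_size >= 1/f_low``) and the output must sample the whole
    recording (``mua_rate >= 1/window_size``).
    """

    band: tuple[float, float] = (200.0, 1500.0)
    window_size: float = 0.3
    mua_rate: float = 100.0
    psd_overlap_fraction: float = 0.5

    def validate(self) -> None:
        f_low, f_high = self.band
        if not 0 < f_low < f_high:
            raise ValueError("need 0 < f_low < f_high")
        if self.window_size < 1.0 / f_low:
            raise ValueError(
                f"window_size ({self.window_size}) must be >= 1/f_low ({1.0 / f_low})")
        if self.mua_rate < 1.0 / self.window_size:
            raise ValueError("mua_rate must be >= 1/window_size")


def logmua_estimate(rec: GridRecording, params: LogMuaParams | None = None) -> GridRecording:
    """Log ratio of in-band to full-spectrum power in a moving window.

    For each output sample a window of ``window_size`` seconds centred on
    the output time is taken (edge windows are truncated, not
    zero-padded) and its Welch power spectral density computed with
    ``nperseg = round(sampling_rate / f_low)`` samples per segment, 50%
    overlap, a Hann window and linear detrending.  The MUA value is the
    mean in-band power divided by the mean power over the whole spectrum,
    and the output signal is its natural logarithm, sampled at
    ``mua_rate``.
    """
    params = params or LogMuaParams()
    params.validate()
    fs = rec.sampling_rate
    f_low, f_high = params.band
    if fs <= 2 * f_high:
        raise ValueError(f"sampling rate {fs} Hz too low for band up to {f_high} Hz")
    nperseg = int(round(fs / f_low))
    wlen = int(round(params.window_size * fs))
    if wlen < nperseg:
        raise ValueError(
            f"window ({wlen} samples) shorter than Welch segment ({nperseg} samples)")
    n_out = int(np.floor((rec.n_samples - 1) / fs * params.mua_rate)) + 1
    out_times = np.arange(n_out) / params.mua_rate  # relative to t_start
    centers = np.round(out_times * fs).astype(int)
    half = wlen // 2
    logmua = np.empty((rec.n_channels, n_out))
    for k, c in enumerate(centers):
        lo = max(0, c - half)
        hi = min(rec.n_samples, c - half + wlen)
        seg = rec.signals[:, lo:hi]
        nps = min(nperseg, seg.shape[1])
        freqs, psd = scipy.signal.welch(
            seg, fs=fs, window="hann", nperseg=nps,
            noverlap=int(np.floor(params.psd_overlap_fraction * nps)),
            detrend="linear", axis=1)
        in_band = (freqs >= f_low) & (freqs <= f_high)
        if not in_band.any():
            raise ValueError("no spectral bins fall inside the band")
        with np.errstate(divide="ignore", invalid="ignore"):
            mua = psd[:, in_band].mean(axis=1) / psd.mean(axis=1)
            logmua[:, k] = np.log(mua)
    out = GridRecording(
        signals=logmua, sampling_rate=params.mua_rate,
        spatial_scale=rec.spatial_scale, coords=rec.coords.copy(),
        t_start=rec.t_start, annotations=dict(rec.annotations),
        history=list(rec.history), active=rec.active.copy(),
    )
    out.annotations["units"] = "log(MUA)"
    out.append_history("logmua_estimate", {
        "band": list(params.band), "window_size": params.window_size,
        "mua_rate": params.mua_rate, "nperseg": nperseg,
        "psd_overlap_fraction": params.psd_overlap_fraction,
        "edge_windows": "truncated"})
    return out


#: Blocks runnable by name from the pipeline orchestrator ("choose any").
BLOCKS = {
    "detrend": detrend,
    "band_pass_filter": band_pass_filter,
    "zscore": zscore,
    "subtract_background": subtract_background,
    "roi_selection": roi_selection,
    "spatial_downsample": spatial_downsample,
    "logmua_estimate": logmua_estimate,
}


def apply_blocks(rec: GridRecording, blocks: list[tuple[str, dict]]) -> GridRecording:
    """Apply named blocks in the user-configured order (choose-any)."""
    out = rec
    for name, kwargs in blocks:
        if name not in BLOCKS:
            raise KeyError(f"unknown processing block {name!r}; "
                           f"available: {sorted(BLOCKS)}")
        if name == "logmua_estimate" and kwargs:
            out = logmua_estimate(out, LogMuaParams(**kwargs))
        else:
            out = BLOCKS[name](out, **kwargs)
    return out
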