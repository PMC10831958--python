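"""Synthetic grid recordings with known ground-truth waves.

Two families of surrogate data are generated:

* calcium-like: slow, smooth transients (difference-of-exponentials
  kernel, GCaMP6f-order time constants) on a low-rate grid, with waves
  sweeping across the sites at a configurable velocity and direction;
* MUA-like: high-rate band-limited noise whose standard deviation is
  stepped up during up states, riding on a stationary broadband
  background, emulating micro-ECoG input to the logMUA estimator.

Every generated recording is paired with a :class:`WaveGroundTruth`
holding the exact per-channel arrival time of each wave, so detectors
and characterization measures can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .core import GridRecording, full_grid_coords


@dataclass
class WaveSpec:
    """One ground-truth wave.

    ``pattern`` is ``"planar"`` (velocity ``v0`` mm/s along direction
    ``theta`` rad) or ``"radial"`` (outward from ``origin`` in mm at
    ``v0``).  ``onset`` (s) anchors the delay map: for a planar wave the
    site (x, y) is reached at ``onset + (x cos0 + y sin0) * scale / v0``,
    for a radial wave at ``onset + ||site_mm - origin|| / v0``.
    """

    pattern: str
    v0: float
    onset: float
    theta: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.pattern not in ("planar", "radial"):
            raise ValueError(f"unknown wave pattern: {self.pattern!r}")
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")


@dataclass
class WaveGroundTruth:
    waves: list[WaveSpec]

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    def trigger_times(self, coords: np.ndarray, spatial_scale: float) -> np.ndarray:
        """True arrival times, shape (n_waves, n_channels), seconds."""
        coords = np.asarray(coords, dtype=float)
        out = np.empty((len(self.waves), len(coords)))
        for i, w in enumerate(self.waves):
            if w.pattern == "planar":
                proj = coords[:, 0] * math.cos(w.theta) + coords[:, 1] * math.sin(w.theta)
                out[i] = w.onset + proj * spatial_scale / w.v0
            else:
                pos = coords * spatial_scale
                dist = np.hypot(pos[:, 0] - w.origin[0], pos[:, 1] - w.origin[1])
                out[i] = w.onset + dist / w.v0
        return out


def planar_wave_train(n_waves: int, period: float, v0: float, theta: float = 0.0,
                      t0: float = 1.0) -> WaveGroundTruth:
    """Regularly spaced planar waves sharing velocity and direction."""
    return WaveGroundTruth([
        WaveSpec("planar", v0=v0, theta=theta, onset=t0 + k * period)
        for k in range(n_waves)
    ])


def radial_wave_train(n_waves: int, period: float, v0: float,
                      origin: tuple[float, float], t0: float = 1.0) -> WaveGroundTruth:
    return WaveGroundTruth([
        WaveSpec("radial", v0=v0, origin=origin, onset=t0 + k * period)
        for k in range(n_waves)
    ])


@dataclass
class CalciumKernel:
    """Causal difference-of-exponentials transient, peak-normalized.

    ``k(t) = amplitude * (exp(-t/tau_d) - exp(-t/tau_r)) / peak`` for
    t >= 0 and zero before.  Defaults (rise 0.1 s, decay 0.5 s) are of
    the order of GCaMP6f indicator dynamics.  The kernel peaks
    ``peak_lag`` seconds after its onset; tests that compare detected
    event times against wave arrival times can compensate with it.
    """

    tau_r: float = 0.1
    tau_d: float = 0.5
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_r < self.tau_d:
            raise ValueError("need 0 < tau_r < tau_d")

    @property
    def peak_lag(self) -> float:
        r, d = self.tau_r, self.tau_d
        return r * d / (d - r) * math.log(d / r)

    @property
    def support(self) -> float:
        """Time after onset beyond which the kernel is < 0.1% of peak."""
        return self.peak_lag + self.tau_d * math.log(1e3)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tc = np.maximum(t, 0.0)  # clamp before exp to avoid overflow at t << 0
        raw = np.where(t >= 0, np.exp(-tc / self.tau_d) - np.exp(-tc / self.tau_r), 0.0)
        peak = (math.exp(-self.peak_lag / self.tau_d)
                - math.exp(-self.peak_lag / self.tau_r))
        return self.amplitude * raw / peak


@dataclass
class MuaKernel:
    """Up-state envelope for MUA-like surrogates: the broadband noise
    standard deviation is multiplied by ``up_gain`` for ``d_up`` seconds
    after each wave arrival."""

    d_up: float = 0.5
    up_gain: float = 5.0


def make_wave_recording(n_x: int, n_y: int, spatial_scale: float, sampling_rate: float,
                        ground_truth: WaveGroundTruth, kernel: CalciumKernel | None = None,
                        noise_sd: float = 0.05, seed: int = 0,
                        duration: float | None = None,
                        t_start: float = 0.0) -> tuple[GridRecording, WaveGroundTruth]:
    """Calcium-like surrogate: each channel is a sum of kernel transients
    at its true wave-arrival times plus white Gaussian noise.

    Raises if consecutive arrivals at any channel fall within the kernel
    support, which would make the ground truth ambiguous.
    """
    kernel = kernel or CalciumKernel()
    coords = full_grid_coords(n_x, n_y)
    tt = ground_truth.trigger_times(coords, spatial_scale)  # (n_waves, n_ch)
    if tt.shape[0] > 1:
        gaps = np.diff(np.sort(tt, axis=0), axis=0)
        if gaps.size and gaps.min() < kernel.support:
            raise ValueError(
                f"waves overlap within the kernel support ({kernel.support:.2f} s); "
                "increase the wave period")
    if duration is None:
        duration = float(tt.max() - t_start + kernel.support)
    n_samples = int(round(duration * sampling_rate))
    times = t_start + np.arange(n_samples) / sampling_rate
    signals = np.zeros((len(coords), n_samples))
    for w in range(tt.shape[0]):
        signals += kernel(times[None, :] - tt[w][:, None])
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        signals += rng.normal(0.0, noise_sd, signals.shape)
    rec = GridRecording(
        signals=signals, sampling_rate=sampling_rate, spatial_scale=spatial_scale,
        coords=coords, t_start=t_start,
        annotations={"units": "a.u.", "source": "synthetic-calcium",
                     "noise_sd": noise_sd, "seed": seed,
                     "kernel": {"tau_r": kernel.tau_r, "tau_d": kernel.tau_d,
                                "amplitude": kernel.amplitude}},
    )
    rec.append_history("make_wave_recording", {
        "n_x": n_x, "n_y": n_y, "spatial_scale": spatial_scale,
        "sampling_rate": sampling_rate, "n_waves": ground_truth.n_waves,
        "noise_sd": noise_sd, "seed": seed})
    return rec, ground_truth


def make_mua_recording(n_x: int, n_y: int, spatial_scale: float, sampling_rate: float,
                       ground_truth: WaveGroundTruth, kernel: MuaKernel | None = None,
                       band: tuple[float, float] = (200.0, 1500.0),
                       noise_sd: float = 1.0, background_sd: float = 2.5,
                       seed: int = 0, duration: float | None = None,
                       t_start: float = 0.0) -> tuple[GridRecording, WaveGroundTruth]:
    """MUA-like surrogate for the logMUA estimator.

    Each channel carries a band-limited (``band``) Gaussian noise
    component -- the multi-unit activity -- whose standard deviation
    (``noise_sd``) is multiplied by ``kernel.up_gain`` during up states
    (from the true wave arrival for ``kernel.d_up`` seconds), on top of a
    stationary broadband background of standard deviation
    ``background_sd``.  The background stands in for the non-spiking
    contributions to an extracellular recording; because it does not
    scale with the up state, the in-band to full-spectrum power ratio
    alternates between two levels and its logarithm becomes bimodal.
    Set ``background_sd=0`` for a pure amplitude-modulated band-limited
    noise process (the up/down variance ratio is then exactly
    ``up_gain**2``).
    """
    kernel = kernel or MuaKernel()
    nyquist = sampling_rate / 2
    if band[1] >= nyquist:
        raise ValueError(f"band_high ({band[1]} Hz) must be below Nyquist ({nyquist} Hz)")
    coords = full_grid_coords(n_x, n_y)
    tt = ground_truth.trigger_times(coords, spatial_scale)
    if duration is None:
        duration = float(tt.max() - t_start + 2 * kernel.d_up)
    n_samples = int(round(duration * sampling_rate))
    times = t_start + np.arange(n_samples) / sampling_rate
    gain = np.ones((len(coords), n_samples))
    for w in range(tt.shape[0]):
        in_up = (times[None, :] >= tt[w][:, None]) & (times[None, :] < tt[w][:, None] + kernel.d_up)
        gain[in_up] = kernel.up_gain
    rng = np.random.default_rng(seed)
    sos = scipy.signal.butter(4, band, btype="band", fs=sampling_rate, output="sos")
    mua = scipy.signal.sosfiltfilt(sos, rng.standard_normal((len(coords), n_samples)),
                                   axis=1)
    mua *= noise_sd / mua.std(axis=1, keepdims=True)
    signals = mua * gain
    if background_sd > 0:
        signals = signals + rng.standard_normal((len(coords), n_samples)) * background_sd
    rec = GridRecording(
        signals=signals, sampling_rate=sampling_rate, spatial_scale=spatial_scale,
        coords=coords, t_start=t_start,
        annotations={"units": "a.u.", "source": "synthetic-mua",
                     "noise_sd": noise_sd, "seed": seed,
                     "up_gain": kernel.up_gain, "d_up": kernel.d_up,
                     "band": list(band), "background_sd": background_sd},
    )
    rec.append_history("make_mua_recording", {
        "n_x": n_x, "n_y": n_y, "spatial_scale": spatial_scale,
        "sampling_rate": sampling_rate, "n_waves": ground_truth.n_waves,
        "up_gain": kernel.up_gain, "d_up": kernel.d_up,
        "noise_sd": noise_sd, "background_sd": background_sd, "seed": seed})
    return rec, ground_truth
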