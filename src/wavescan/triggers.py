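"""Detection of down->up state transitions ("triggers") per channel.

Three interchangeable detectors are provided:

* threshold -- amplitude-threshold crossings, with the threshold set
  globally, from a two-Gaussian fit of the amplitude distribution
  (central minimum of the fitted mixture), or from a Gaussian fit of the
  low-activity peak only (mean + SIGMA_FACTOR * sd).  Suited to signals
  with sharp, bimodal state separation such as logMUA.
* hilbert -- upward crossings of the analytic-signal phase through a
  threshold (default -pi/2, the beginning of the upstroke), retained
  only when followed by a phase-0 peak.  Suited to slow, smooth signals
  such as calcium transients; requires detrended, z-scored input.
* minima -- local minima preceding a dominant peak, with refinement
  rules for peak height, peak separation, and a required monotonic rise
  after the minimum.

Threshold and phase crossing times are linearly interpolated between
samples; minima are reported at sample resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.signal
from sklearn.cluster import KMeans

from .core import GridRecording, TriggerSet


class BimodalFitError(ValueError):
    """Raised when the amplitude distribution has no usable bimodal
    structure (caller may fall back to the left-peak fit)."""


# ------------------------------------------------------------ thresholds

def _two_gaussians(x, w, mu1, sd1, mu2, sd2):
    g1 = w * np.exp(-0.5 * ((x - mu1) / sd1) ** 2) / (sd1 * math.sqrt(2 * math.pi))
    g2 = (1 - w) * np.exp(-0.5 * ((x - mu2) / sd2) ** 2) / (sd2 * math.sqrt(2 * math.pi))
    return g1 + g2


def fit_bimodal_threshold(samples: np.ndarray, bins: int | str = "fd") -> float:
    """Threshold separating low and high activity states.

    Fits the sum of two Gaussians to the amplitude histogram (k-means
    initialization of the two means) and returns the location of the
    minimum of the fitted mixture between the two means.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if len(samples) < 100:
        raise ValueError("need at least 100 samples for a bimodal fit")
    hist, edges = np.histogram(samples, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(samples.reshape(-1, 1))
    mus = np.sort(km.cluster_centers_.ravel())
    sd0 = samples.std() / 2 or 1.0
    p0 = [0.5, mus[0], sd0, mus[1], sd0]
    try:
        popt, _ = scipy.optimize.curve_fit(
            _two_gaussians, centers, hist, p0=p0,
            bounds=([0.0, -np.inf, 1e-12, -np.inf, 1e-12],
                    [1.0, np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise BimodalFitError(f"no bimodal structure: fit failed ({exc})") from exc
    w, mu1, sd1, mu2, sd2 = popt
    if mu1 > mu2:
        mu1, sd1, mu2, sd2 = mu2, sd2, mu1, sd1
        w = 1 - w
    if mu2 - mu1 < sd1 + sd2:
        raise BimodalFitError(
            f"no bimodal structure: means {mu1:.3g}, {mu2:.3g} closer than "
            f"the sum of the fitted widths {sd1 + sd2:.3g}")
    res = scipy.optimize.minimize_scalar(
        lambda x: _two_gaussians(x, w, mu1, sd1, mu2, sd2),
        bounds=(mu1, mu2), method="bounded")
    return float(res.x)


def fit_left_peak_threshold(samples: np.ndarray, sigma_factor: float,
                            bins: int | str = "fd") -> float:
    """Threshold from a Gaussian fit of the low-activity peak only.

    Locates the first dominant peak of the amplitude histogram, fits a
    Gaussian to the samples left of it (mean anchored at the peak, sd
    from the left-half second moment) and returns
    ``mean + sd * sigma_factor``.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    hist, edges = np.histogram(samples, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # high prominence excludes counting-noise wiggles on the flank of a mode
    peaks, _ = scipy.signal.find_peaks(hist, prominence=0.25 * hist.max())
    dominant = [p for p in peaks if hist[p] >= 0.5 * hist.max()]
    if not dominant:
        if hist.argmax() in (0, len(hist) - 1):
            raise ValueError("dominant peak lies at the histogram edge")
        dominant = [int(hist.argmax())]
    p = dominant[0]
    # quadratic interpolation around the peak bin for a sub-bin mode estimate
    if 0 < p < len(hist) - 1:
        y0, y1, y2 = hist[p - 1], hist[p], hist[p + 1]
        denom = (y0 - 2 * y1 + y2)
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        mu0 = centers[p] + shift * (centers[1] - centers[0])
    else:
        raise ValueError("dominant peak lies at the histogram edge")
    left = samples[samples <= mu0]
    if len(left) < 2:
        raise ValueError("no samples left of the peak")
    sd0 = math.sqrt(np.mean((left - mu0) ** 2))
    # refine by fitting a Gaussian to the left flank of the histogram
    sel = centers <= mu0 + sd0 / 2
    if sel.sum() >= 5:
        def gauss(x, a, mu, sd):
            return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
        try:
            popt, _ = scipy.optimize.curve_fit(
                gauss, centers[sel], hist[sel], p0=[hist[p], mu0, sd0],
                bounds=([0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=10000)
            _, mu0, sd0 = popt
        except (RuntimeError, ValueError):
            pass  # fall back to the moment estimate
    return float(mu0 + sd0 * sigma_factor)


@dataclass
class ThresholdParams:
    """Configuration of the threshold detector.

    ``method``: ``fixed`` (use ``fixed_value`` for all channels),
    ``bimodal_fit`` (per-channel two-Gaussian fit) or ``left_peak``
    (per-channel low-state fit with ``sigma_factor``).  With
    ``fallback_to_left_peak`` a failed bimodal fit falls back to the
    left-peak variant instead of raising.
    """

    method: str = "bimodal_fit"
    fixed_value: float = 0.0
    sigma_factor: float = 3.0
    bins: int | str = "fd"
    fallback_to_left_peak: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "bimodal_fit", "left_peak"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.sigma_factor <= 0:
            raise ValueError("sigma_factor must be > 0")


def _interp_crossings(x: np.ndarray, thr: float, times: np.ndarray,
                      direction: str) -> np.ndarray:
    """Linearly interpolated threshold-crossing times."""
    if direction == "up":
        idx = np.flatnonzero((x[:-1] < thr) & (x[1:] >= thr))
    else:
        idx = np.flatnonzero((x[:-1] >= thr) & (x[1:] < thr))
    if len(idx) == 0:
        return np.empty(0)
    frac = (thr - x[idx]) / (x[idx + 1] - x[idx])
    dt = times[1] - times[0]
    return times[idx] + frac * dt


def detect_threshold_triggers(rec: GridRecording,
                              params: ThresholdParams | None = None) -> TriggerSet:
    """Upward and downward threshold crossings per channel.

    Up and down times alternate by construction.  Channels where the
    threshold fit fails (and no fallback is enabled) yield empty trigger
    lists with a warning.
    """
    params = params or ThresholdParams()
    times = rec.times
    up: list[np.ndarray] = []
    down: list[np.ndarray] = []
    for c in range(rec.n_channels):
        x = rec.signals[c]
        if not rec.active[c] or not np.isfinite(x).all():
            up.append(np.empty(0))
            down.append(np.empty(0))
            continue
        try:
            if params.method == "fixed":
                thr = params.fixed_value
            elif params.method == "bimodal_fit":
                try:
                    thr = fit_bimodal_threshold(x, bins=params.bins)
                except BimodalFitError:
                    if not params.fallback_to_left_peak:
                        raise
                    thr = fit_left_peak_threshold(x, params.sigma_factor, bins=params.bins)
            else:
                thr = fit_left_peak_threshold(x, params.sigma_factor, bins=params.bins)
        except (BimodalFitError, ValueError) as exc:
            warnings.warn(f"channel {c}: threshold fit failed ({exc}); no triggers",
                          RuntimeWarning, stacklevel=2)
            up.append(np.empty(0))
            down.append(np.empty(0))
            continue
        up.append(_interp_crossings(x, thr, times, "up"))
        down.append(_interp_crossings(x, thr, times, "down"))
    ts = TriggerSet(up=up, down=down,
                    source={"detector": "threshold", "method": params.method,
                            "sigma_factor": params.sigma_factor})
    return ts


def filter_min_state_durations(ts: TriggerSet, min_up: float,
                               min_down: float) -> TriggerSet:
    """Drop up states shorter than ``min_up`` and down states shorter
    than ``min_down`` (both bounding events are removed, which merges the
    neighbouring states); alternation is preserved."""
    if ts.down is None:
        raise ValueError("duration filtering needs both up and down times")
    new_up, new_down = [], []
    for tu, td in zip(ts.up, ts.down):
        events = sorted([(t, "u") for t in tu] + [(t, "d") for t in td])
        changed = True
        while changed:
            changed = False
            for i in range(len(events) - 1):
                (t0, k0), (t1, k1) = events[i], events[i + 1]
                if k0 == "u" and k1 == "d" and t1 - t0 < min_up:
                    del events[i:i + 2]
                    changed = True
                    break
                if k0 == "d" and k1 == "u" and t1 - t0 < min_down:
                    del events[i:i + 2]
                    changed = True
                    break
        new_up.append(np.array([t for t, k in events if k == "u"]))
        new_down.append(np.array([t for t, k in events if k == "d"]))
    out = TriggerSet(up=new_up, down=new_down, source=dict(ts.source))
    out.source["min_up"] = min_up
    out.source["min_down"] = min_down
    return out


# ------------------------------------------------------------ hilbert

def detect_hilbert_triggers(rec: GridRecording,
                            phase_threshold: float = -np.pi / 2) -> TriggerSet:
    """Upward crossings of the analytic-signal phase.

    The phase convention is ``angle`` in (-pi, pi] with phase 0 at the
    signal peak, so the default threshold -pi/2 marks the beginning of
    the upstroke.  A crossing is kept only if the phase reaches 0 (a
    peak) before the next threshold crossing, which rejects sub-cycle
    wobbles.  Input should be detrended and z-scored so the analytic
    phase is meaningful.
    """
    times = rec.times
    dt = 1.0 / rec.sampling_rate
    up: list[np.ndarray] = []
    for c in range(rec.n_channels):
        x = rec.signals[c]
        if not rec.active[c] or not np.isfinite(x).all() or np.ptp(x) == 0:
            up.append(np.empty(0))
            continue
        phase = np.angle(scipy.signal.hilbert(x))
        d = np.diff(phase)
        genuine = d < np.pi  # exclude the -pi/+pi wrap-around jumps
        thr_cross = np.flatnonzero(
            (phase[:-1] < phase_threshold) & (phase[1:] >= phase_threshold) & genuine)
        zero_cross = np.flatnonzero((phase[:-1] < 0) & (phase[1:] >= 0) & genuine)
        kept = []
        for i, idx in enumerate(thr_cross):
            nxt = thr_cross[i + 1] if i + 1 < len(thr_cross) else len(phase)
            peaks_between = zero_cross[(zero_cross > idx) & (zero_cross < nxt)]
            if len(peaks_between) == 0:
                continue
            frac = (phase_threshold - phase[idx]) / (phase[idx + 1] - phase[idx])
            kept.append(times[idx] + frac * dt)
        up.append(np.asarray(kept))
    return TriggerSet(up=up, source={"detector": "hilbert",
                                     "phase_threshold": phase_threshold})


# ------------------------------------------------------------ minima

@dataclass
class MinimaParams:
    """Configuration of the minima detector.

    ``window_len``: length (s) of the moving window in which the relative
    peak-height threshold is evaluated (no universal default exists; set
    it to a few expected wave periods).
    ``peak_threshold``: fraction of the local (window) signal range a
    maximum must exceed to count as a wave peak.
    ``min_peak_distance``: minimum separation (s) between accepted peaks,
    matching the characteristic rhythm of the phenomenon.
    ``rise_interval``: the signal must rise monotonically for this long
    (s) after a candidate minimum.
    """

    window_len: float
    min_peak_distance: float
    rise_interval: float
    peak_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("window_len", "min_peak_distance", "rise_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def detect_minima_triggers(rec: GridRecording, params: MinimaParams) -> TriggerSet:
    """Local minima that precede an accepted ("good") maximum.

    Rules: (1) maxima must exceed a relative height threshold evaluated
    in a moving window; (2) accepted maxima are separated by at least
    ``min_peak_distance``; (3) a candidate minimum must be followed by a
    monotonic rise for ``rise_interval``.  If several candidate minima
    fall between two accepted maxima, the last one before the following
    good maximum is selected.
    """
    fs = rec.sampling_rate
    wlen = max(3, int(round(params.window_len * fs)))
    dist = max(1, int(round(params.min_peak_distance * fs)))
    rise = max(1, int(round(params.rise_interval * fs)))
    times = rec.times
    up: list[np.ndarray] = []
    for c in range(rec.n_channels):
        x = rec.signals[c]
        if not rec.active[c] or not np.isfinite(x).all() or np.ptp(x) == 0:
            up.append(np.empty(0))
            continue
        maxima, _ = scipy.signal.find_peaks(x, distance=dist)
        good_max = []
        half = wlen // 2
        for p in maxima:
            lo = max(0, p - half)
            hi = min(len(x), p + half)
            w = x[lo:hi]
            if x[p] >= w.min() + params.peak_threshold * (w.max() - w.min()):
                good_max.append(p)
        # weak local minima: the last point of a flat stretch before a rise
        # counts, so an onset from a noise-free baseline is detectable
        minima = np.flatnonzero((x[1:-1] <= x[:-2]) & (x[1:-1] < x[2:])) + 1
        triggers = []
        prev = 0
        for p in good_max:
            cands = [m for m in minima if prev <= m < p]
            cands = [m for m in cands
                     if m + rise < len(x) and np.all(np.diff(x[m:m + rise + 1]) > 0)]
            if cands:
                triggers.append(times[cands[-1]])  # last minimum before the good maximum
            prev = p
        up.append(np.asarray(triggers))
    return TriggerSet(up=up, source={
        "detector": "minima", "window_len": params.window_len,
        "min_peak_distance": params.min_peak_distance,
        "rise_interval": params.rise_interval,
        "peak_threshold": params.peak_threshold})
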