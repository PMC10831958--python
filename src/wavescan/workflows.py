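"""End-to-end analysis workflows on synthetic recordings.

These functions chain the individual stages the way a user of the
library would for a calibration or benchmarking study: simulate ->
process -> detect triggers -> cluster waves -> optical flow ->
characterize.  They are used by the test-bench studies (parameter
recovery, detector benchmarking, downsampling) and serve as worked
examples of the API.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import characterize as _char
from . import processing as _proc
from . import synthetic as _syn
from . import triggers as _trig
from . import waves as _wav
from .core import GridRecording, TriggerSet, WaveSet


@dataclass
class WaveAnalysis:
    """Bundle of every intermediate result of one analysis run."""

    recording: GridRecording
    processed: GridRecording
    triggers: TriggerSet
    waves: WaveSet
    flow: "_wav.FlowField"
    ground_truth: _syn.WaveGroundTruth | None = None

    def delay_map(self, wave_id: int) -> _char.WaveDelayMap:
        return _char.build_delay_map(self.waves, wave_id, self.processed)


def analyze_recording(rec: GridRecording, expected_v0: float,
                      band: tuple[float, float] = (0.1, 5.0),
                      detector: str = "hilbert",
                      minima_params: "_trig.MinimaParams | None" = None,
                      flow_params: "_wav.OpticalFlowParams | None" = None,
                      clustering: "_wav.WaveClusteringParams | None" = None,
                      flow_at_triggers_only: bool = True,
                      ground_truth: _syn.WaveGroundTruth | None = None) -> WaveAnalysis:
    """Standard calcium-style analysis path for one grid recording.

    The recording is detrended, band-pass filtered and z-scored, triggers
    are detected (Hilbert phase by default), clustered with parameters
    calibrated to ``expected_v0``, deduplicated, and the phase optical
    flow is computed (by default only around the trigger frames, which is
    where directions are sampled).
    """
    proc = _proc.zscore(_proc.band_pass_filter(_proc.detrend(rec), *band))
    if detector == "hilbert":
        ts = _trig.detect_hilbert_triggers(proc)
    elif detector == "minima":
        ts = _trig.detect_minima_triggers(proc, minima_params)
    else:
        raise ValueError(f"unknown detector {detector!r} for calcium-style data")
    clustering = clustering or _wav.WaveClusteringParams.calibrated(
        expected_v0, rec.sampling_rate, rec.spatial_scale)
    ws = _wav.cluster_triggers_to_waves(ts, proc, clustering)
    ws = _wav.dedupe_channel_triggers(ws)
    field = _wav.phase_field(proc)
    idx = _wav.trigger_frame_indices(ts, proc) if flow_at_triggers_only else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        flow = _wav.compute_optical_flow(field, flow_params, frame_indices=idx)
    return WaveAnalysis(recording=rec, processed=proc, triggers=ts, waves=ws,
                        flow=flow, ground_truth=ground_truth)


def wave_measures(analysis: WaveAnalysis, velocity_method: str = "plane_fit",
                  velocity_window: int = 5) -> dict:
    """Channel-wise velocities, per-wave planarity and mean direction.

    Velocities are capped at the standard plausibility limit before
    pooling.  Returns arrays pooled over all detected waves plus the
    per-wave lists.
    """
    dirs, n_skipped = _wav.wave_directions_from_flow(
        analysis.waves, analysis.flow, analysis.processed)
    velocities, planarities, directions = [], [], []
    rec = analysis.processed
    for w in analysis.waves.wave_ids:
        dm = analysis.delay_map(int(w))
        v = _char.channel_velocity(dm, method=velocity_method,
                                   window=velocity_window)
        kept, _ = _char.cap_velocities(v[np.isfinite(v)])
        velocities.append(kept)
        vecs = dirs.get(int(w), np.empty((0, 2)))
        if len(vecs):
            planarities.append(_char.planarity(vecs))
            directions.append(_char.circular_mean_direction(vecs))
    return {
        "velocities": np.concatenate(velocities) if velocities else np.empty(0),
        "planarity": np.asarray(planarities),
        "directions": np.asarray(directions),
        "n_waves": analysis.waves.n_waves,
        "n_skipped_directions": n_skipped,
    }


def planar_recovery_run(v0: float, theta: float, seed: int, n_waves: int = 5,
                        period: float = 4.0, n_x: int = 20, n_y: int = 20,
                        spatial_scale: float = 0.05, sampling_rate: float = 25.0,
                        noise_sd: float = 0.05) -> dict:
    """Simulate a planar wave train and measure it with the standard path."""
    gt = _syn.planar_wave_train(n_waves, period, v0, theta=theta)
    rec, gt = _syn.make_wave_recording(n_x, n_y, spatial_scale, sampling_rate,
                                       gt, noise_sd=noise_sd, seed=seed)
    analysis = analyze_recording(rec, expected_v0=v0, ground_truth=gt)
    return wave_measures(analysis)


def radial_recovery_run(v0: float, seed: int, n_waves: int = 5,
                        period: float = 4.0, n_x: int = 20, n_y: int = 20,
                        spatial_scale: float = 0.05, sampling_rate: float = 25.0,
                        noise_sd: float = 0.05) -> dict:
    """Simulate radial (outward from the grid centre) waves and measure
    them; the symmetric flow makes these the low-planarity fixture."""
    origin = ((n_x - 1) * spatial_scale / 2, (n_y - 1) * spatial_scale / 2)
    gt = _syn.radial_wave_train(n_waves, period, v0, origin=origin)
    rec, gt = _syn.make_wave_recording(n_x, n_y, spatial_scale, sampling_rate,
                                       gt, noise_sd=noise_sd, seed=seed)
    analysis = analyze_recording(rec, expected_v0=v0, ground_truth=gt)
    return wave_measures(analysis)


def mixed_downsampling_run(factor: int, seed: int = 1, n_planar: int = 2,
                           n_radial: int = 6, period: float = 4.0,
                           v0_planar: float = 15.0, v0_radial: float = 10.0,
                           n_x: int = 20, n_y: int = 20,
                           spatial_scale: float = 0.05,
                           sampling_rate: float = 25.0,
                           noise_sd: float = 0.05) -> dict:
    """Downsampling study: a mixed planar + radial wave set analysed at a
    reduced spatial resolution.

    Emulates recording the same activity with coarser sensors: the
    recording is spatially downsampled by ``factor`` (block averaging)
    before the standard analysis path runs with clustering parameters
    re-calibrated to the new spatial scale.  Complex (radial) patterns
    lose their local structure at coarse resolution, so the median
    planarity rises while the number of detectable waves cannot grow.
    """
    origin = ((n_x - 1) * spatial_scale / 2, (n_y - 1) * spatial_scale / 2)
    specs = []
    t0 = 1.0
    for k in range(n_planar + n_radial):
        if k % 4 == 0 and k // 4 < n_planar:
            specs.append(_syn.WaveSpec("planar", v0=v0_planar,
                                       theta=0.0, onset=t0 + k * period))
        else:
            specs.append(_syn.WaveSpec("radial", v0=v0_radial, origin=origin,
                                       onset=t0 + k * period))
    gt = _syn.WaveGroundTruth(specs)
    rec, gt = _syn.make_wave_recording(n_x, n_y, spatial_scale, sampling_rate,
                                       gt, noise_sd=noise_sd, seed=seed)
    coarse = _proc.spatial_downsample(rec, factor)
    analysis = analyze_recording(coarse, expected_v0=v0_radial, ground_truth=gt)
    return wave_measures(analysis)


def logmua_study(up_gain: float, seed: int, n_x: int = 8, n_y: int = 8,
                 d_up: float = 0.5, period: float = 2.0, n_waves: int = 4,
                 v0: float = 30.0, spatial_scale: float = 0.55,
                 sampling_rate: float = 5000.0, duration: float | None = None,
                 background_sd: float = 2.5) -> tuple[GridRecording, _syn.WaveGroundTruth]:
    """Generate an MUA-like recording and return its logMUA signal.

    The returned recording holds log(band power / full power) at the
    standard estimator settings; up states appear as the high mode of a
    bimodal amplitude distribution once ``up_gain`` is large enough.
    """
    gt = _syn.planar_wave_train(n_waves, period, v0)
    rec, gt = _syn.make_mua_recording(
        n_x, n_y, spatial_scale, sampling_rate, gt,
        kernel=_syn.MuaKernel(d_up=d_up, up_gain=up_gain),
        background_sd=background_sd, seed=seed, duration=duration)
    logmua = _proc.logmua_estimate(rec)
    return logmua, gt
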