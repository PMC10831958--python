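"""Trigger clustering, optical flow, and wave-mode grouping."""

import warnings

import numpy as np
import pytest

import wavescan as wsc
from wavescan.core import NOISE
from wavescan.waves import (OpticalFlowParams, WaveClusteringParams,
                            cluster_wave_modes, trigger_delay_matrix)


class TestTimeSpaceRatio:
    @pytest.mark.parametrize("v0,rate,scale,expected", [
        (10.0, 25.0, 0.05, 8.0),
        (20.0, 25.0, 0.05, 16.0),
        (30.0, 25.0, 0.05, 24.0),
    ])
    def test_printed_calcium_values(self, v0, rate, scale, expected):
        assert wsc.compute_time_space_ratio(v0, rate, scale) == pytest.approx(expected)

    def test_identity_case(self):
        assert wsc.compute_time_space_ratio(2.5, 50.0, 0.05) == pytest.approx(1.0)

    def test_doubling_v0_doubles_ratio(self):
        r1 = wsc.compute_time_space_ratio(7.3, 25.0, 0.05)
        r2 = wsc.compute_time_space_ratio(14.6, 25.0, 0.05)
        assert r2 == pytest.approx(2 * r1)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            wsc.compute_time_space_ratio(0.0, 25.0, 0.05)


class TestClustering:
    def _detect(self, rec, gt):
        proc = wsc.zscore(wsc.detrend(rec, order=0))
        return wsc.detect_hilbert_triggers(proc)

    def test_noiseless_wave_train_recovered_exactly(self, planar_noiseless):
        rec, gt = planar_noiseless
        ts = self._detect(rec, gt)
        params = WaveClusteringParams.calibrated(15.0, rec.sampling_rate,
                                                 rec.spatial_scale)
        ws = wsc.cluster_triggers_to_waves(ts, rec, params)
        assert ws.n_waves == gt.n_waves
        assert not np.any(ws.labels == NOISE)
        tt = gt.trigger_times(rec.coords, rec.spatial_scale)
        for w in ws.wave_ids:
            chans, times = ws.wave(w)
            assert len(chans) == rec.n_channels
            # wave ids are ordered by onset, so wave w matches truth row w
            assert np.abs(np.sort(times) - np.sort(tt[w])).max() < 0.1

    def test_single_trigger_is_noise(self):
        rec = wsc.GridRecording(np.zeros((16, 100)), 25.0, 0.05,
                                wsc.full_grid_coords(4, 4))
        ts = wsc.TriggerSet(up=[np.array([1.0])] + [np.array([])] * 15)
        ws = wsc.cluster_triggers_to_waves(
            ts, rec, WaveClusteringParams(1.0, 2.0, min_samples_per_wave=5))
        assert ws.n_waves == 0
        assert list(ws.labels) == [NOISE]

    def test_two_separated_bursts_give_two_clusters(self):
        rec = wsc.GridRecording(np.zeros((16, 10000)), 25.0, 0.05,
                                wsc.full_grid_coords(4, 4))
        eps = 2.0
        gap = 10 * eps / (rec.sampling_rate * 1.0)  # 10x eps in scaled time
        ts = wsc.TriggerSet(up=[np.array([1.0, 1.0 + gap]) for _ in range(16)])
        ws = wsc.cluster_triggers_to_waves(
            ts, rec, WaveClusteringParams(1.0, eps, min_samples_per_wave=5))
        assert ws.n_waves == 2

    def test_invariant_to_global_time_shift(self, planar_noiseless):
        rec, gt = planar_noiseless
        ts = self._detect(rec, gt)
        params = WaveClusteringParams.calibrated(15.0, rec.sampling_rate,
                                                 rec.spatial_scale)
        ws1 = wsc.cluster_triggers_to_waves(ts, rec, params)
        shifted = wsc.TriggerSet(up=[np.asarray(t) + 3.21 for t in ts.up])
        ws2 = wsc.cluster_triggers_to_waves(shifted, rec, params)
        np.testing.assert_array_equal(ws1.labels, ws2.labels)

    def test_min_samples_respected(self, planar_noiseless):
        rec, gt = planar_noiseless
        ts = self._detect(rec, gt)
        params = WaveClusteringParams.calibrated(15.0, rec.sampling_rate,
                                                 rec.spatial_scale)
        ws = wsc.cluster_triggers_to_waves(ts, rec, params)
        for w in ws.wave_ids:
            assert (ws.labels == w).sum() >= params.min_samples_per_wave


class TestDedupe:
    def _ws(self):
        return wsc.WaveSet(channels=[0, 1, 1, 2], times=[1.0, 1.1, 1.2, 1.3],
                           labels=[0, 0, 0, 0])

    def test_wave_without_duplicates_unchanged(self):
        ws = wsc.WaveSet(channels=[0, 1, 2], times=[1.0, 1.1, 1.2],
                         labels=[0, 0, 0])
        out = wsc.dedupe_channel_triggers(ws)
        np.testing.assert_array_equal(out.labels, ws.labels)

    def test_earliest_kept(self):
        out = wsc.dedupe_channel_triggers(self._ws())
        chans, times = out.wave(0)
        assert sorted(chans) == [0, 1, 2]
        assert 1.2 not in times

    def test_keep_all_defers_error_to_delay_map(self):
        rec = wsc.GridRecording(np.zeros((4, 10)), 25.0, 0.05,
                                wsc.full_grid_coords(2, 2))
        out = wsc.dedupe_channel_triggers(self._ws(), policy="keep_all")
        np.testing.assert_array_equal(out.labels, self._ws().labels)
        with pytest.raises(ValueError, match="multiple triggers"):
            wsc.build_delay_map(out, 0, rec)


class TestPhaseField:
    def test_common_sine_gives_uniform_phase(self):
        fs = 50.0
        t = np.arange(500) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        rec = wsc.GridRecording(np.tile(x, (9, 1)), fs, 0.05,
                                wsc.full_grid_coords(3, 3))
        field = wsc.phase_field(rec)
        assert field.shape == (500, 3, 3)
        for frame in field[50:450:37]:
            assert np.nanmax(np.abs(frame - frame[0, 0])) < 1e-9

    def test_planar_wave_has_constant_phase_gradient(self):
        fs = 50.0
        t = np.arange(1000) / fs
        shifts = 0.02  # seconds per site
        sig = np.stack([np.sin(2 * np.pi * 1.0 * (t - s * shifts))
                        for s in range(5)])
        rec = wsc.GridRecording(np.tile(sig, (5, 1)), fs, 0.05,
                                wsc.full_grid_coords(5, 5))
        field = wsc.phase_field(rec)
        grad = np.diff(field[300], axis=1)  # d(phase)/dx at one frame
        # a site delayed by tau lags in phase by omega*tau
        expected = -2 * np.pi * 1.0 * shifts
        np.testing.assert_allclose(grad, expected, atol=1e-6)

    def test_masked_site_is_nan(self, small_rec):
        t = np.arange(small_rec.n_samples) / small_rec.sampling_rate
        small_rec.signals[:] = np.sin(2 * np.pi * 0.5 * t)
        mask = np.ones(small_rec.grid_shape, bool)
        mask[0, 0] = False
        rec = wsc.roi_selection(small_rec, mask)
        field = wsc.phase_field(rec)
        assert np.all(np.isnan(field[:, 0, 0]))
        assert np.isfinite(field[:, 1, 1]).all()


def _phase_plane(n_frames=12, n=16, speed=1.0, direction=0.0, k=0.4):
    """Translating planar phase field: phase = k*(x cos + y sin - speed*t)."""
    yy, xx = np.mgrid[0:n, 0:n]
    proj = xx * np.cos(direction) + yy * np.sin(direction)
    return np.stack([k * (proj - speed * t) for t in range(n_frames)])


class TestOpticalFlow:
    def test_static_field_gives_zero_flow(self):
        field = np.tile(_phase_plane(1)[0], (6, 1, 1))
        flow = wsc.compute_optical_flow(field)
        assert np.nanmax(np.abs(flow.u)) < 1e-9
        assert np.nanmax(np.abs(flow.v)) < 1e-9

    def test_translating_plane_recovers_displacement(self):
        # phase = k*(x - t): iso-phase contours move along +x at 1 site/frame
        field = _phase_plane(speed=1.0)
        flow = wsc.compute_optical_flow(field)
        interior = flow.u[3:-3, 4:-4, 4:-4]
        assert np.nanmean(interior) == pytest.approx(1.0, rel=0.1)
        ang = np.degrees(np.arctan2(flow.v[3:-3, 4:-4, 4:-4], interior))
        assert np.nanmax(np.abs(ang)) < 5.0

    def test_huge_alpha_gives_uniform_flow(self):
        rng = np.random.default_rng(0)
        field = _phase_plane() + 0.05 * rng.normal(size=(12, 16, 16))
        flow = wsc.compute_optical_flow(field, OpticalFlowParams(alpha=1e4))
        u = flow.u[5]
        mag = np.nanmean(np.hypot(flow.u[5], flow.v[5]))
        assert np.nanvar(u) < 1e-3 * max(mag, 1e-12) ** 2 + 1e-12

    def test_phase_wrap_invariance(self):
        field = _phase_plane()
        flow1 = wsc.compute_optical_flow(field)
        flow2 = wsc.compute_optical_flow(field + 2 * np.pi)
        np.testing.assert_allclose(flow1.u, flow2.u, atol=1e-9)
        np.testing.assert_allclose(flow1.v, flow2.v, atol=1e-9)

    def test_wrap_seam_handled(self):
        """A phase ramp crossing +-pi must not produce spurious flow at
        the seam."""
        field = _phase_plane(k=0.8, speed=0.5)  # spans beyond (-pi, pi]
        wrapped = np.angle(np.exp(1j * field))
        flow = wsc.compute_optical_flow(wrapped)
        flow_raw = wsc.compute_optical_flow(field)
        np.testing.assert_allclose(flow.u, flow_raw.u, atol=1e-6)

    def test_frame_subset_matches_full_solution(self):
        field = _phase_plane()
        full = wsc.compute_optical_flow(
            field, OpticalFlowParams(smooth_sigma=(0.0, 1.0, 1.0)))
        sub = wsc.compute_optical_flow(
            field, OpticalFlowParams(smooth_sigma=(0.0, 1.0, 1.0)),
            frame_indices=[4, 5])
        np.testing.assert_allclose(sub.u[4], full.u[4], atol=1e-6)
        assert np.all(np.isnan(sub.u[0]))

    def test_nan_sites_do_not_poison_neighbours(self):
        field = _phase_plane()
        field[:, 8, 8] = np.nan
        flow = wsc.compute_optical_flow(field)
        assert np.all(np.isnan(flow.u[:, 8, 8]))
        assert np.isfinite(flow.u[5, 2:6, 2:6]).all()


class TestWaveDirections:
    def _planar_setup(self):
        gt = wsc.planar_wave_train(3, 4.0, 15.0, theta=0.0)
        rec, gt = wsc.make_wave_recording(12, 12, 0.05, 25.0, gt,
                                          noise_sd=0.0, seed=5)
        proc = wsc.zscore(wsc.detrend(rec, order=0))
        ts = wsc.detect_hilbert_triggers(proc)
        params = WaveClusteringParams.calibrated(15.0, 25.0, 0.05)
        ws = wsc.dedupe_channel_triggers(
            wsc.cluster_triggers_to_waves(ts, proc, params))
        field = wsc.phase_field(proc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            flow = wsc.compute_optical_flow(field)
        return rec, ws, flow

    def test_planar_wave_directions_along_propagation(self):
        rec, ws, flow = self._planar_setup()
        dirs, n_skipped = wsc.wave_directions_from_flow(ws, flow, rec)
        all_vecs = np.vstack([dirs[int(w)] for w in ws.wave_ids])
        angles = np.degrees(np.arctan2(all_vecs[:, 1], all_vecs[:, 0]))
        assert np.abs(np.median(angles)) < 10.0

    def test_zero_flow_sites_skipped_and_counted(self):
        rec = wsc.GridRecording(np.zeros((9, 50)), 25.0, 0.05,
                                wsc.full_grid_coords(3, 3))
        ws = wsc.WaveSet(channels=np.arange(9), times=np.full(9, 1.0),
                         labels=np.zeros(9, int))
        flow = wsc.FlowField(u=np.zeros((50, 3, 3)), v=np.zeros((50, 3, 3)))
        dirs, n_skipped = wsc.wave_directions_from_flow(ws, flow, rec)
        assert n_skipped == 9
        assert dirs[0].shape == (0, 2)


class TestWaveModes:
    def _two_family_waveset(self):
        """5 waves sweeping +x and 5 sweeping -x on a 4x4 grid."""
        coords = wsc.full_grid_coords(4, 4)
        chans, times, labels = [], [], []
        for w in range(10):
            onset = 1.0 + 2.0 * w
            delays = coords[:, 0] * 0.05 if w % 2 == 0 else (3 - coords[:, 0]) * 0.05
            chans.extend(range(16))
            times.extend(onset + delays)
            labels.extend([w] * 16)
        return wsc.WaveSet(channels=chans, times=times, labels=labels)

    def test_two_direction_families_recovered(self):
        ws = self._two_family_waveset()
        out = cluster_wave_modes(ws, n_modes=2, n_channels=16, seed=0)
        modes = np.array([out.mode_labels[w] for w in range(10)])
        assert len(set(modes[0::2])) == 1
        assert len(set(modes[1::2])) == 1
        assert modes[0] != modes[1]

    def test_single_mode_covers_all_waves(self):
        ws = self._two_family_waveset()
        out = cluster_wave_modes(ws, n_modes=1, n_channels=16, seed=0)
        assert set(out.mode_labels.values()) == {0}

    def test_identical_waves_degenerate_split_terminates(self):
        coords = wsc.full_grid_coords(4, 4)
        chans, times, labels = [], [], []
        for w in range(4):
            chans.extend(range(16))
            times.extend(1.0 + 2.0 * w + coords[:, 0] * 0.05)
            labels.extend([w] * 16)
        ws = wsc.WaveSet(channels=chans, times=times, labels=labels)
        out = cluster_wave_modes(ws, n_modes=2, n_channels=16, seed=0)
        assert out.params["mode_clustering"]["inertia"] < 1e-12

    def test_more_modes_than_waves_rejected(self):
        ws = self._two_family_waveset()
        with pytest.raises(ValueError, match="exceeds"):
            cluster_wave_modes(ws, n_modes=11, n_channels=16)

    def test_missing_channels_imputed_late(self):
        ws = wsc.WaveSet(channels=[0, 1, 2], times=[1.0, 1.1, 1.3],
                         labels=[0, 0, 0])
        mat = trigger_delay_matrix(ws, n_channels=5, imputation="max")
        np.testing.assert_allclose(mat[0, :3], [0.0, 0.1, 0.3])
        np.testing.assert_allclose(mat[0, 3:], 0.3)
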