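"""Wave measures: delay maps, velocity, planarity, intervals, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import wavescan as wsc
from wavescan.characterize import WaveDelayMap


def _delay_map_from_truth(v0, theta, n=12, scale=0.05):
    yy, xx = np.mgrid[0:n, 0:n]
    T = (xx * np.cos(theta) + yy * np.sin(theta)) * scale / v0
    return WaveDelayMap(T=T - T.min(), spatial_scale=scale, wave_id=0)


class TestDelayMap:
    def test_planar_truth_is_linear_in_x(self, planar_noiseless):
        rec, gt = planar_noiseless
        tt = gt.trigger_times(rec.coords, rec.spatial_scale)
        ws = wsc.WaveSet(channels=np.arange(rec.n_channels), times=tt[0],
                         labels=np.zeros(rec.n_channels, int))
        dm = wsc.build_delay_map(ws, 0, rec)
        expected = rec.coords[:, 0] * rec.spatial_scale / 15.0
        np.testing.assert_allclose(
            dm.T[rec.coords[:, 1], rec.coords[:, 0]], expected, atol=1e-12)
        assert np.nanmin(dm.T) == 0.0

    def test_minimum_is_always_zero(self):
        rng = np.random.default_rng(4)
        rec = wsc.GridRecording(np.zeros((16, 10)), 25.0, 0.05,
                                wsc.full_grid_coords(4, 4))
        ws = wsc.WaveSet(channels=np.arange(16),
                         times=5.0 + rng.uniform(0, 1, 16),
                         labels=np.zeros(16, int))
        dm = wsc.build_delay_map(ws, 0, rec)
        assert np.nanmin(dm.T) == 0.0
        assert np.nanmin(dm.T) >= 0.0

    def test_too_few_sites_rejected(self):
        rec = wsc.GridRecording(np.zeros((4, 10)), 25.0, 0.05,
                                wsc.full_grid_coords(2, 2))
        ws = wsc.WaveSet(channels=[0, 1], times=[1.0, 1.1], labels=[0, 0])
        with pytest.raises(ValueError, match="fewer than 3"):
            wsc.build_delay_map(ws, 0, rec)


class TestChannelVelocity:
    def test_axis_aligned_plane_exact(self):
        dm = _delay_map_from_truth(15.0, 0.0)
        v = wsc.channel_velocity(dm)
        np.testing.assert_allclose(v[1:-1, 1:-1], 15.0, rtol=1e-12)

    def test_diagonal_plane_matches_brute_force_gradient(self):
        dm = _delay_map_from_truth(15.0, np.pi / 4)
        v = wsc.channel_velocity(dm)
        # oracle: brute-force finite differences via numpy on the interior
        gy, gx = np.gradient(dm.T, dm.spatial_scale)
        oracle = 1.0 / np.hypot(gx, gy)
        np.testing.assert_allclose(v[1:-1, 1:-1], oracle[1:-1, 1:-1], rtol=1e-9)
        np.testing.assert_allclose(v[1:-1, 1:-1], 15.0, rtol=1e-9)

    def test_constant_map_is_undefined_not_infinite(self):
        dm = WaveDelayMap(T=np.zeros((5, 5)), spatial_scale=0.05, wave_id=0)
        v = wsc.channel_velocity(dm)
        assert np.all(np.isnan(v))

    def test_plane_fit_matches_central_on_linear_map(self):
        dm = _delay_map_from_truth(10.0, np.pi / 3)
        v_c = wsc.channel_velocity(dm, method="central")
        v_p = wsc.channel_velocity(dm, method="plane_fit", window=5)
        np.testing.assert_allclose(v_p[2:-2, 2:-2], v_c[2:-2, 2:-2], rtol=1e-9)


class TestCapVelocities:
    def test_all_below_cap_identity(self):
        vals = np.array([10.0, 50.0, 119.0])
        kept, flagged = wsc.cap_velocities(vals)
        np.testing.assert_array_equal(kept, vals)
        assert not flagged.any()

    def test_outlier_flagged_not_lost(self):
        kept, flagged = wsc.cap_velocities(np.array([10.0, 500.0]))
        np.testing.assert_array_equal(kept, [10.0])
        np.testing.assert_array_equal(flagged, [False, True])

    def test_infinite_cap_is_identity(self):
        vals = np.array([10.0, 500.0, 1e6])
        kept, flagged = wsc.cap_velocities(vals, cap=np.inf)
        np.testing.assert_array_equal(kept, vals)


class TestPlanarity:
    def test_identical_vectors_reach_one(self):
        vecs = np.tile([0.3, 0.4], (100, 1))
        assert wsc.planarity(vecs) == pytest.approx(1.0, abs=1e-12)

    def test_opposing_pairs_cancel_to_zero(self):
        vecs = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        assert wsc.planarity(vecs) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_unit_pair(self):
        vecs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert wsc.planarity(vecs) == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_all_zero_vectors_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wsc.planarity(np.zeros((5, 2)))

    @settings(deadline=None, max_examples=200)
    @given(hnp.arrays(np.float64, st.tuples(st.integers(1, 40), st.just(2)),
                      elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_bounds_on_arbitrary_vector_sets(self, vecs):
        norms = np.linalg.norm(vecs, axis=1)
        if norms.sum() == 0:
            return
        p = wsc.planarity(vecs)
        assert 0.0 <= p <= 1.0 + 1e-12


class TestInterwaveIntervals:
    def test_regular_triggers(self):
        ws = wsc.WaveSet(channels=[0, 0, 0], times=[0.0, 2.0, 4.0],
                         labels=[0, 1, 2])
        iwi = wsc.interwave_intervals(ws)
        np.testing.assert_allclose(iwi[0], [2.0, 2.0])

    def test_single_wave_empty(self):
        ws = wsc.WaveSet(channels=[0], times=[1.0], labels=[0])
        assert len(wsc.interwave_intervals(ws)[0]) == 0

    def test_generator_period_recovered(self, planar_noiseless):
        rec, gt = planar_noiseless
        tt = gt.trigger_times(rec.coords, rec.spatial_scale)
        chans = np.tile(np.arange(rec.n_channels), gt.n_waves)
        times = tt.ravel()
        labels = np.repeat(np.arange(gt.n_waves), rec.n_channels)
        ws = wsc.WaveSet(channels=chans, times=times, labels=labels)
        iwi = wsc.interwave_intervals(ws)
        all_intervals = np.concatenate(list(iwi.values()))
        assert np.median(all_intervals) == pytest.approx(4.0, abs=1 / 25.0)


class TestWaveWiseAggregate:
    def test_uniform_velocities_pass_through(self):
        row = wsc.wave_wise_aggregate(np.full(10, 12.0), np.tile([1.0, 0.0], (10, 1)))
        assert row["velocity"] == pytest.approx(12.0)
        assert row["direction"] == pytest.approx(0.0)

    def test_opposing_directions_flagged_undefined(self):
        vecs = np.array([[1.0, 0.0], [-1.0, 0.0]])
        row = wsc.wave_wise_aggregate(np.array([10.0]), vecs)
        assert np.isnan(row["direction"]) and row["direction_undefined"]

    def test_capped_values_excluded_from_mean(self):
        row = wsc.wave_wise_aggregate(np.array([10.0, 20.0, 500.0]),
                                      np.tile([1.0, 0.0], (3, 1)))
        assert row["velocity"] == pytest.approx(15.0)
        assert row["n_capped"] == 1

    def test_empty_wave_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wsc.wave_wise_aggregate(np.array([]), np.empty((0, 2)))


class TestHedges:
    def test_identical_groups_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert wsc.hedges_effect_size(a, a) == 0.0

    def test_worked_example(self):
        assert wsc.hedges_effect_size([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 40)
        es = wsc.hedges_effect_size(a, b)
        assert wsc.hedges_effect_size(3.7 * a, 3.7 * b) == pytest.approx(es)

    def test_matches_brute_force_formula_on_random_pairs(self):
        """Direct transcription of the pooled-sigma formula as oracle."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            na, nb = rng.integers(2, 50, 2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), na)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), nb)
            sa2 = np.sum((a - a.mean()) ** 2) / (na - 1)
            sb2 = np.sum((b - b.mean()) ** 2) / (nb - 1)
            pooled = np.sqrt(((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2))
            oracle = abs(a.mean() - b.mean()) / pooled
            assert abs(wsc.hedges_effect_size(a, b) - oracle) < 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            wsc.hedges_effect_size([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="zero"):
            wsc.hedges_effect_size([2.0, 2.0], [2.0, 2.0])


class TestKde:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(8)
        grid, dens = wsc.kde_summary(rng.normal(size=2000))
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_interwave_bandwidth_rule(self):
        """For the interval measure the kernel size is exactly 0.2 sd."""
        rng = np.random.default_rng(9)
        values = rng.normal(4.0, 1.0, 500)
        import scipy.stats
        kde_ours = scipy.stats.gaussian_kde(values, bw_method=0.2)
        grid, dens = wsc.kde_summary(values, measure_kind="interwave_interval",
                                     grid=np.linspace(0, 8, 200))
        np.testing.assert_allclose(dens, kde_ours(np.linspace(0, 8, 200)),
                                   atol=1e-12)

    def test_two_point_sample_is_finite_bimodal(self):
        # the fixed 0.2*sd interval kernel is narrow enough to resolve
        # both points as separate modes
        grid, dens = wsc.kde_summary(np.array([0.0, 10.0]),
                                     measure_kind="interwave_interval",
                                     grid=np.linspace(-5, 15, 400))
        assert np.isfinite(dens).all()
        import scipy.signal
        assert len(scipy.signal.find_peaks(dens)[0]) == 2

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            wsc.kde_summary(np.array([1.0, 1.0, 1.0]))


class TestTables:
    def _analysis(self):
        from wavescan import workflows as wf
        gt = wsc.planar_wave_train(3, 4.0, 15.0)
        rec, gt = wsc.make_wave_recording(8, 8, 0.05, 25.0, gt,
                                          noise_sd=0.0, seed=11)
        rec.annotations["anesthetic"] = "ketamine"
        return wf.analyze_recording(rec, expected_v0=15.0, ground_truth=gt)

    def test_wave_wise_one_row_per_wave(self, tmp_path):
        a = self._analysis()
        table = wsc.emit_table(a.processed, a.waves, tmp_path / "t.csv",
                               flow=a.flow, variant="wave_wise")
        assert len(table) == a.waves.n_waves
        assert {"wave_id", "velocity", "direction", "planarity"} <= \
            set(table.frame.columns)
        assert (tmp_path / "t.csv").exists()
        assert (tmp_path / "t.csv.json").exists()

    def test_channel_wise_row_count_bounded(self, tmp_path):
        a = self._analysis()
        table = wsc.characterize_waves(a.processed, a.waves, flow=a.flow,
                                       variant="channel_wise")
        assert len(table) <= a.waves.n_waves * a.processed.n_channels
        assert table.frame.groupby("wave_id").size().max() <= a.processed.n_channels

    def test_annotation_propagates_to_every_row(self):
        a = self._analysis()
        table = wsc.characterize_waves(a.processed, a.waves, flow=a.flow,
                                       variant="wave_wise",
                                       annotation_keys=["anesthetic"])
        assert (table.frame["anesthetic"] == "ketamine").all()

    def test_unknown_annotation_lists_available(self):
        a = self._analysis()
        with pytest.raises(KeyError, match="available"):
            wsc.characterize_waves(a.processed, a.waves, flow=a.flow,
                                   annotation_keys=["nonexistent"])
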