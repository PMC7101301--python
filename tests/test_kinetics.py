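import numpy as np
import pytest

from voxdose import (ActivitySeries, ActivityVolume, RoiMask, Tac, VoxelGrid,
                     build_phantom, effective_half_life, fit_monoexp,
                     merge_tia_maps, roi_tac, simulate_series, tia_from_fit,
                     voxelwise_tia)
from voxdose.kinetics import (KBQ_H_TO_DECAYS, STATUS_FAILED,
                              STATUS_FALLBACK, STATUS_OK, _profile_sse)
from voxdose.phantom import PhantomSpec, sphere

TIMES = np.array([4.0, 24.0, 48.0, 72.0])


def _uniform_series(grid, conc_by_time):
    vols = [ActivityVolume(grid, np.full(tuple(grid.dims), c), t)
            for t, c in conc_by_time]
    return ActivitySeries(volumes=vols)


def _box_mask(grid, n=100):
    labels = np.zeros(tuple(grid.dims), dtype=np.int32)
    labels.ravel()[:n] = 1
    return RoiMask(grid=grid, labels=labels, names={1: ("roi", "liver")})


class TestRoiTac:
    def test_uniform_roi_sums_concentration_times_volume(self):
        g = VoxelGrid(dims=(10, 10, 10))
        series = _uniform_series(g, [(4.0, 10.0), (24.0, 10.0)])
        mask = _box_mask(g, n=100)
        tac = roi_tac(series, mask, 1)
        # 100 voxels * 10 kBq/mL * 0.1099022 mL
        assert tac.activities[0] == pytest.approx(109.9022, abs=1e-3)

    def test_zero_activity_gives_zero_tac(self):
        g = VoxelGrid(dims=(6, 6, 6))
        series = _uniform_series(g, [(4.0, 0.0), (24.0, 0.0)])
        tac = roi_tac(series, _box_mask(g, 10), 1)
        assert np.all(tac.activities == 0)

    def test_absent_label_errors(self):
        g = VoxelGrid(dims=(6, 6, 6))
        series = _uniform_series(g, [(4.0, 1.0), (24.0, 1.0)])
        with pytest.raises(KeyError):
            roi_tac(series, _box_mask(g, 10), 99)


class TestFitMonoexp:
    def test_exact_model_recovered(self):
        y = 100.0 * np.exp(-TIMES / 50.0)
        fit = fit_monoexp(Tac(TIMES, y))
        assert fit.status == STATUS_OK
        assert fit.a0 == pytest.approx(100.0, rel=1e-6)
        assert fit.tau_h == pytest.approx(50.0, rel=1e-6)

    def test_matches_dense_grid_search_oracle_on_noisy_tac(self):
        rng = np.random.default_rng(7)
        y = 100.0 * np.exp(-TIMES / 50.0) + rng.normal(0, 2.0, TIMES.size)
        fit = fit_monoexp(Tac(TIMES, y))
        # independent oracle: dense 2-D search over (tau) via the profiled
        # SSE on a fine logarithmic grid
        taus = np.exp(np.linspace(np.log(1.0), np.log(2000.0), 200_000))
        sse, a0 = _profile_sse(TIMES, y, taus)
        k = int(np.argmin(sse))
        assert fit.tau_h == pytest.approx(taus[k], rel=1e-3)
        assert fit.a0 == pytest.approx(a0[k], rel=1e-3)
        assert fit.sse <= sse[k] * (1 + 1e-9)

    def test_flat_samples_fall_back(self):
        fit = fit_monoexp(Tac(TIMES, np.array([10.0, 10.0, 10.0, 10.0])))
        assert fit.status == STATUS_FALLBACK
        assert not (fit.tau_h > 0)

    def test_all_nonpositive_fails(self):
        fit = fit_monoexp(Tac(TIMES, np.zeros(4)))
        assert fit.status == STATUS_FAILED

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        y = 50.0 * np.exp(-TIMES / 30.0) + rng.normal(0, 1.0, 4)
        f1 = fit_monoexp(Tac(TIMES, y))
        f2 = fit_monoexp(Tac(TIMES, 7.0 * y))
        assert f2.tau_h == pytest.approx(f1.tau_h, rel=1e-6)
        assert f2.a0 == pytest.approx(7.0 * f1.a0, rel=1e-6)

    def test_time_shift_property(self):
        """Shifting all times by +d multiplies a0 by exp(d/tau), tau fixed."""
        rng = np.random.default_rng(11)
        y = 90.0 * np.exp(-TIMES / 60.0) + rng.normal(0, 0.5, 4)
        f1 = fit_monoexp(Tac(TIMES, y))
        d = 10.0
        f2 = fit_monoexp(Tac(TIMES + d, y))
        assert f2.tau_h == pytest.approx(f1.tau_h, rel=1e-5)
        assert f2.a0 == pytest.approx(f1.a0 * np.exp(d / f1.tau_h), rel=1e-5)


class TestTia:
    def test_analytic_integral_and_units(self):
        fit = fit_monoexp(Tac(TIMES, 100.0 * np.exp(-TIMES / 50.0)))
        tia = tia_from_fit(fit)
        assert tia == pytest.approx(100.0 * 50.0 * KBQ_H_TO_DECAYS, rel=1e-6)
        assert tia == pytest.approx(1.8e10, rel=1e-6)

    def test_tau_linearity(self):
        f1 = fit_monoexp(Tac(TIMES, 10.0 * np.exp(-TIMES / 25.0)))
        f2 = fit_monoexp(Tac(TIMES, 10.0 * np.exp(-TIMES / 50.0)))
        assert tia_from_fit(f2) == pytest.approx(2 * tia_from_fit(f1), rel=1e-5)

    def test_non_ok_fit_rejected(self):
        fit = fit_monoexp(Tac(TIMES, np.zeros(4)))
        with pytest.raises(ValueError):
            tia_from_fit(fit)


class TestEffectiveHalfLife:
    def test_ln2_relation(self):
        fit = fit_monoexp(Tac(TIMES, 10.0 * np.exp(-TIMES / 100.0)))
        assert effective_half_life(fit) == pytest.approx(69.31, abs=0.01)

    def test_exceeding_physical_half_life_warns_not_clamps(self):
        tau = 600.3
        fit = fit_monoexp(Tac(TIMES, 10.0 * np.exp(-TIMES / tau)))
        with pytest.warns(UserWarning, match="exceeds the physical"):
            t_half = effective_half_life(fit)
        assert t_half == pytest.approx(416.1, abs=0.1)

    def test_short_tau_limit(self):
        fit = fit_monoexp(Tac(np.array([1.0, 2.0, 3.0, 4.0]),
                              100.0 * np.exp(-np.array([1.0, 2.0, 3.0, 4.0]) / 0.5)))
        assert effective_half_life(fit) == pytest.approx(0.5 * np.log(2), rel=1e-4)


class TestVoxelwiseTia:
    def _phantom_series(self, noise=0.0, seed=0):
        g = VoxelGrid(dims=(16, 16, 16))
        c = (4.79 * 7.5,) * 3
        spec = PhantomSpec(grid=g, structures=[
            sphere("les", "liver", c, 14.0, 120.0, 60.0)])
        truth = build_phantom(spec)
        series = simulate_series(truth, noise_scale=noise, seed=seed)
        return truth, series

    def test_uniform_roi_gives_equal_fractions(self):
        truth, series = self._phantom_series()
        fit = fit_monoexp(roi_tac(series, truth.mask, 1))
        tia = voxelwise_tia(series, truth.mask, 1, fit)
        idx = truth.mask.labels == 1
        n = int(idx.sum())
        assert np.allclose(tia.fractions[idx], 1.0 / n, rtol=1e-9)

    def test_fractions_sum_to_one(self):
        truth, series = self._phantom_series(noise=0.05, seed=5)
        fit = fit_monoexp(roi_tac(series, truth.mask, 1))
        tia = voxelwise_tia(series, truth.mask, 1, fit)
        assert tia.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constructed_three_to_one_ratio(self):
        """Two-voxel ROI with voxel TIAs in ratio 3:1 -> fractions 0.75/0.25."""
        g = VoxelGrid(dims=(4, 4, 4))
        shape = tuple(g.dims)
        labels = np.zeros(shape, dtype=np.int32)
        labels[0, 0, 0] = 1
        labels[0, 0, 1] = 1
        mask = RoiMask(grid=g, labels=labels, names={1: ("pair", "liver")})
        vols = []
        for t in TIMES:
            v = np.zeros(shape)
            v[0, 0, 0] = 30.0 * np.exp(-t / 40.0)   # 3x the amplitude
            v[0, 0, 1] = 10.0 * np.exp(-t / 40.0)
            vols.append(ActivityVolume(g, v, t))
        series = ActivitySeries(volumes=vols)
        fit = fit_monoexp(roi_tac(series, mask, 1))
        tia = voxelwise_tia(series, mask, 1, fit)
        assert tia.fractions[0, 0, 0] == pytest.approx(0.75, abs=1e-9)
        assert tia.fractions[0, 0, 1] == pytest.approx(0.25, abs=1e-9)

    def test_roi_tia_equals_voxel_sum_on_noise_free_data(self):
        truth, series = self._phantom_series()
        fit = fit_monoexp(roi_tac(series, truth.mask, 1))
        tia = voxelwise_tia(series, truth.mask, 1, fit)
        assert tia.voxel_decays.sum() == pytest.approx(
            tia_from_fit(fit), rel=1e-6)
        # and the voxel_sum scaling mode agrees on noise-free input
        tia2 = voxelwise_tia(series, truth.mask, 1, fit,
                             absolute_scale="voxel_sum")
        assert tia2.voxel_decays.sum() == pytest.approx(
            tia.voxel_decays.sum(), rel=1e-6)

    def test_merge_preserves_totals(self):
        truth, series = self._phantom_series()
        fit = fit_monoexp(roi_tac(series, truth.mask, 1))
        tia = voxelwise_tia(series, truth.mask, 1, fit)
        merged = merge_tia_maps([tia])
        assert np.array_equal(merged.voxel_decays, tia.voxel_decays)
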