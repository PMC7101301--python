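import numpy as np
import pytest

from voxdose import (DensityMap, SourceMap, TransportConfig,
                     VoxelGrid, equilibrium_dose, hu_to_density, kernel_dose,
                     point_kernel, run_mc)
from voxdose.mc_dose import region_mean_se
from voxdose.nuclide import KEV_TO_J

from voxdose.testing import mono_beta_nuclide


def point_source(dims=(9, 9, 9), spacing=(4.79,) * 3, decays=1e6):
    g = VoxelGrid(dims=dims, spacing_mm=spacing)
    p = np.zeros(dims)
    p[tuple(d // 2 for d in dims)] = 1.0
    return (SourceMap(grid=g, probabilities=p, total_decays=decays),
            DensityMap(grid=g, values=np.ones(dims)))


class TestHuToDensity:
    @pytest.mark.parametrize("hu,rho", [(0.0, 1.0), (-1000.0, 0.001),
                                        (500.0, 1.5), (1000.0, 2.0),
                                        (5000.0, 3.0)])
    def test_linear_map_with_clamps(self, hu, rho):
        g = VoxelGrid(dims=(2, 2, 2))
        d = hu_to_density(np.full((2, 2, 2), hu), g)
        assert np.all(d.values == pytest.approx(rho))

    def test_nonfinite_rejected(self):
        g = VoxelGrid(dims=(2, 2, 2))
        hu = np.zeros((2, 2, 2))
        hu[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            hu_to_density(hu, g)


class TestRunMcBasics:
    def test_zero_decays_gives_zero_dose(self, nuclide):
        src, dens = point_source(decays=0.0)
        dm = run_mc(src, dens, nuclide,
                    TransportConfig(n_histories=100, seed=0))
        assert np.all(dm.dose_gy == 0)

    def test_local_beta_point_source_closed_form(self):
        """Photons off + local betas + single-line spectrum: the emission
        voxel receives exactly N * E / m and nothing else."""
        nuc = mono_beta_nuclide(e_kev=100.0)
        src, dens = point_source(decays=1e6)
        cfg = TransportConfig(n_histories=500, seed=1, photons_on=False,
                              beta_mode="local")
        dm = run_mc(src, dens, nuc, cfg)
        mass_kg = src.grid.voxel_volume_ml * 1e-3
        expect = 1e6 * 100.0 * KEV_TO_J / mass_kg
        c = tuple(d // 2 for d in src.grid.dims)
        assert dm.dose_gy[c] == pytest.approx(expect, rel=1e-12)
        assert np.count_nonzero(dm.dose_gy) == 1

    def test_reproducible_bit_identical(self, nuclide):
        src, dens = point_source()
        cfg = TransportConfig(n_histories=5000, seed=7, photons_on=True)
        d1 = run_mc(src, dens, nuclide, cfg)
        d2 = run_mc(src, dens, nuclide, cfg)
        assert np.array_equal(d1.dose_gy, d2.dose_gy)
        assert np.array_equal(d1.rel_se, d2.rel_se)

    def test_seed_changes_output(self, nuclide):
        src, dens = point_source()
        d1 = run_mc(src, dens, nuclide,
                    TransportConfig(n_histories=5000, seed=1))
        d2 = run_mc(src, dens, nuclide,
                    TransportConfig(n_histories=5000, seed=2))
        assert not np.array_equal(d1.dose_gy, d2.dose_gy)

    def test_energy_conservation_no_photons_local(self, nuclide):
        src, dens = point_source()
        dm = run_mc(src, dens, nuclide,
                    TransportConfig(n_histories=3000, seed=3, photons_on=False))
        assert dm.energy_deposited_kev == pytest.approx(
            dm.energy_emitted_kev, rel=1e-12)

    def test_energy_balance_with_photons(self, nuclide):
        src, dens = point_source()
        dm = run_mc(src, dens, nuclide,
                    TransportConfig(n_histories=20000, seed=4, photons_on=True))
        total = dm.energy_deposited_kev + dm.meta["escaped_kev"]
        assert total == pytest.approx(dm.energy_emitted_kev, rel=1e-9)
        assert dm.energy_deposited_kev < dm.energy_emitted_kev  # some escape

    def test_track_betas_conserve_energy_and_spread(self, nuclide):
        src, dens = point_source()
        dm = run_mc(src, dens, nuclide,
                    TransportConfig(n_histories=3000, seed=5, photons_on=False,
                                    beta_mode="track"))
        total = dm.energy_deposited_kev + dm.meta["escaped_kev"]
        assert total == pytest.approx(dm.energy_emitted_kev, rel=1e-9)
        assert np.count_nonzero(dm.dose_gy) > 1  # tracks cross voxel faces

    def test_lighter_voxels_get_higher_beta_dose(self, nuclide):
        """Uniform-density mode vs a lung-like density: mass scaling
        raises the local beta dose in light voxels."""
        dims = (7, 7, 7)
        g = VoxelGrid(dims=dims)
        probs = np.full(dims, 1.0 / np.prod(dims))
        src = SourceMap(grid=g, probabilities=probs, total_decays=1e6)
        lung = DensityMap(grid=g, values=np.full(dims, 0.3))
        cfg = TransportConfig(n_histories=20000, seed=6, photons_on=False)
        d_patient = run_mc(src, lung, nuclide, cfg)
        cfg_u = TransportConfig(n_histories=20000, seed=6, photons_on=False,
                                uniform_density=True)
        d_uniform = run_mc(src, lung, nuclide, cfg_u)
        sel = d_uniform.dose_gy > 0
        assert np.all(d_patient.dose_gy[sel] > d_uniform.dose_gy[sel])


class TestEquilibrium:
    def test_closed_form_scalings(self, nuclide):
        g = VoxelGrid(dims=(3, 3, 3))
        assert equilibrium_dose(0.0, nuclide, g) == 0.0
        d1 = equilibrium_dose(1e6, nuclide, g, density_g_cm3=1.0)
        d2 = equilibrium_dose(1e6, nuclide, g, density_g_cm3=2.0)
        assert d1 == pytest.approx(2 * d2, rel=1e-12)
        # formula arithmetic: decays * E_per_decay * J/keV / mass
        e = nuclide.total_energy_per_decay_kev
        mass = g.voxel_volume_ml * 1e-3
        assert d1 == pytest.approx(1e6 * e * KEV_TO_J / mass, rel=1e-12)

    def test_uniform_phantom_reaches_equilibrium_at_center(self, nuclide):
        """Self-irradiating uniform water phantom, photons on: the
        central-region dose matches the infinite-medium closed form
        within 3 batch standard errors (phantom half-width ~5 photon
        mean free paths)."""
        n = 41
        g = VoxelGrid(dims=(n, n, n), spacing_mm=(10.0, 10.0, 10.0))
        src = SourceMap(grid=g, probabilities=np.full((n, n, n), 1.0 / n**3),
                        total_decays=1e9)
        dens = DensityMap(grid=g, values=np.ones((n, n, n)))
        cfg = TransportConfig(n_histories=100_000, seed=3, photons_on=True,
                              keep_batches=True)
        dm = run_mc(src, dens, nuclide, cfg)
        eq = equilibrium_dose(1e9 / n**3, nuclide, g)
        c, h = n // 2, 2
        idx = np.arange(n**3).reshape(n, n, n)[
            c - h:c + h + 1, c - h:c + h + 1, c - h:c + h + 1].ravel()
        mean, se = region_mean_se(dm, idx)
        assert abs(mean - eq) < 3 * se


class TestConvergence:
    def test_batch_se_scales_as_inverse_sqrt_histories(self, nuclide):
        dims = (9, 9, 9)
        g = VoxelGrid(dims=dims)
        src = SourceMap(grid=g, probabilities=np.full(dims, 1.0 / np.prod(dims)),
                        total_decays=1e6)
        dens = DensityMap(grid=g, values=np.ones(dims))
        ses = []
        for n in (4000, 40000):
            dm = run_mc(src, dens, nuclide,
                        TransportConfig(n_histories=n, seed=8, photons_on=False))
            sel = dm.dose_gy > 0
            ses.append((dm.rel_se[sel] * dm.dose_gy[sel]).mean())
        ratio = ses[0] / ses[1]
        assert ratio == pytest.approx(np.sqrt(10), rel=0.2)


class TestKernel:
    def test_kernel_total_bounded_by_emitted_energy(self, nuclide):
        cfg = TransportConfig(n_histories=20000, seed=9)
        k = point_kernel(nuclide, cfg, halfsize=8)
        assert k.sum() <= nuclide.total_energy_per_decay_kev * (1 + 1e-9)
        assert k.sum() > nuclide.mean_beta_energy_kev  # betas all local

    def test_kernel_matches_direct_mc_for_point_source(self, nuclide):
        """MC self-consistency: convolving with the precomputed kernel
        reproduces a direct point-source run within 3 sigma."""
        dims = (17, 17, 17)
        src, dens = point_source(dims=dims, decays=1e8)
        cfg_direct = TransportConfig(n_histories=40000, seed=11)
        direct = run_mc(src, dens, nuclide, cfg_direct)
        cfg_kernel = TransportConfig(n_histories=40000, seed=22)
        kd = kernel_dose(src, nuclide, cfg_kernel, halfsize=8)
        sel = (direct.dose_gy > 1e-3 * direct.dose_gy.max())
        se_abs = direct.rel_se[sel] * direct.dose_gy[sel]
        # both maps carry comparable MC noise -> combined sigma ~ sqrt(2)*se;
        # allow the chance exceedances expected over hundreds of voxels
        z = np.abs(direct.dose_gy[sel] - kd.dose_gy[sel]) / \
            (np.sqrt(2) * se_abs + 1e-12 * direct.dose_gy.max())
        assert np.mean(z <= 3.0) >= 0.985
        assert z.max() < 6.0

    def test_two_point_source_is_sum_of_shifted_points(self, nuclide):
        dims = (15, 15, 15)
        g = VoxelGrid(dims=dims)
        cfg = TransportConfig(n_histories=10000, seed=12)
        k = point_kernel(nuclide, cfg, halfsize=7)
        p1 = np.zeros(dims); p1[5, 7, 7] = 1.0
        p2 = np.zeros(dims); p2[9, 7, 7] = 1.0
        s1 = SourceMap(grid=g, probabilities=p1, total_decays=1e6)
        s2 = SourceMap(grid=g, probabilities=p2, total_decays=1e6)
        both = SourceMap(grid=g, probabilities=(p1 + p2) / 2, total_decays=2e6)
        d1 = kernel_dose(s1, nuclide, cfg, kernel=k)
        d2 = kernel_dose(s2, nuclide, cfg, kernel=k)
        d12 = kernel_dose(both, nuclide, cfg, kernel=k)
        assert np.allclose(d12.dose_gy, d1.dose_gy + d2.dose_gy,
                           rtol=1e-9, atol=1e-12 * d12.dose_gy.max())

    def test_nonuniform_density_rejected(self, nuclide):
        dims = (9, 9, 9)
        src, _ = point_source(dims=dims)
        rho = np.ones(dims); rho[0, 0, 0] = 2.0
        dens = DensityMap(grid=src.grid, values=rho)
        cfg = TransportConfig(n_histories=100, seed=1)
        with pytest.raises(ValueError, match="uniform"):
            kernel_dose(src, nuclide, cfg, density=dens)
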