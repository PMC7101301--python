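"""Voxel Monte Carlo absorbed-dose engine.

Physics model (deliberately minimal, every simplification documented):

* Betas: the Lu-177 beta range (< 2.3 mm in soft tissue) is below the
  voxel size of a quantitative SPECT grid, so the default ``local`` mode
  deposits the full sampled beta energy in the emission voxel.  The
  optional ``track`` mode transports the electron along an isotropic
  straight line, spending its water CSDA range scaled by 1/density and
  depositing energy uniformly per water-equivalent path length.
* Photons: photoelectric absorption (full local deposit) and incoherent
  Compton scattering (Klein-Nishina free-electron sampling via Kahn's
  method; recoil electron deposited on the spot).  No coherent
  scattering, no bremsstrahlung.  Free paths are sampled by exact ray
  stepping through the density grid with mu = (mu/rho)_water * rho;
  material composition is approximated by water everywhere.
* Uncertainty: histories are split into batches with independent,
  deterministically derived RNG streams; the per-voxel relative standard
  error is the batch standard error of the mean.

Dose is deposited energy (J) divided by voxel mass (kg); the per-history
tally is scaled by total decays / histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .core import VoxelGrid, check_same_grid
from .nuclide import KEV_TO_J, NuclideData

DENSITY_FLOOR = 0.001
DENSITY_CEIL = 3.0

ELECTRON_REST_KEV = 510.99895


@dataclass
class DensityMap:
    grid: VoxelGrid
    values: np.ndarray  # g/cm^3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError("density shape does not match grid")
        if np.any(self.values < DENSITY_FLOOR - 1e-12):
            raise ValueError(f"density below floor {DENSITY_FLOOR}")


@dataclass
class SourceMap:
    """Per-voxel emission probabilities plus the absolute decay count."""

    grid: VoxelGrid
    probabilities: np.ndarray
    total_decays: float

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.shape != tuple(self.grid.dims):
            raise ValueError("probability shape does not match grid")
        if self.total_decays < 0:
            raise ValueError("total_decays must be >= 0")
        s = self.probabilities.sum()
        if self.total_decays > 0 and abs(s - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {s}, not 1")

    @classmethod
    def from_tia(cls, tia_map) -> "SourceMap":
        dec = np.asarray(tia_map.voxel_decays, dtype=np.float64)
        total = float(dec.sum())
        probs = dec / total if total > 0 else np.zeros_like(dec)
        return cls(grid=tia_map.grid, probabilities=probs, total_decays=total)


@dataclass
class TransportConfig:
    n_histories: int = 100_000
    seed: int = 0
    batches: int = 10
    beta_mode: str = "local"         # "local" | "track"
    photons_on: bool = True
    photon_cutoff_kev: float = 20.0
    uniform_density: bool = False
    keep_batches: bool = False       # retain per-batch dose for region SEs

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.photon_cutoff_kev < 1.0:
            raise ValueError("photon cutoff must be >= 1 keV")
        if self.beta_mode not in ("local", "track"):
            raise ValueError(f"unknown beta_mode {self.beta_mode!r}")
        if self.batches < 2:
            raise ValueError("need >= 2 batches for an uncertainty estimate")


@dataclass
class DoseMap:
    grid: VoxelGrid
    dose_gy: np.ndarray
    rel_se: np.ndarray
    histories: int
    seed: int
    energy_emitted_kev: float = 0.0    # per-history-normalized bookkeeping
    energy_deposited_kev: float = 0.0
    meta: dict = field(default_factory=dict)


def hu_to_density(hu: np.ndarray, grid: VoxelGrid) -> DensityMap:
    """Single-segment CT calibration rho = 1 + HU/1000, clamped.

    The linear map is exact for water (HU 0) by construction and a
    serviceable approximation for soft tissue, lung and bone on the
    coarse grids used here; a site-specific calibration table can be
    substituted by constructing DensityMap directly.
    """
    hu = np.asarray(hu, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU volume contains non-finite values")
    rho = np.clip(1.0 + hu / 1000.0, DENSITY_FLOOR, DENSITY_CEIL)
    return DensityMap(grid=grid, values=rho)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _sample_discrete(rng, values: np.ndarray, probs: np.ndarray, n: int) -> np.ndarray:
    cdf = np.cumsum(probs)
    cdf /= cdf[-1]
    return values[np.searchsorted(cdf, rng.random(n), side="right")]


def _isotropic_directions(rng, n: int) -> np.ndarray:
    mu = 2.0 * rng.random(n) - 1.0
    phi = 2.0 * np.pi * rng.random(n)
    s = np.sqrt(1.0 - mu * mu)
    return np.stack([s * np.cos(phi), s * np.sin(phi), mu], axis=1)


def _kahn_compton(rng, e_kev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample Compton scatter from the Klein-Nishina law (Kahn's method).

    Returns (scattered energy keV, cos of scattering angle).
    """
    alpha = e_kev / ELECTRON_REST_KEV
    n = alpha.size
    x = np.empty(n)
    done = np.zeros(n, dtype=bool)
    while not done.all():
        idx = np.flatnonzero(~done)
        a = alpha[idx]
        r1, r2, r3 = rng.random((3, idx.size))
        branch1 = r1 <= (1 + 2 * a) / (9 + 2 * a)
        xx = np.where(branch1, 1 + 2 * a * r2, (1 + 2 * a) / (1 + 2 * a * r2))
        cos_t = 1 - (xx - 1) / a
        acc1 = r3 <= 4 * (1 / xx - 1 / xx**2)
        acc2 = r3 <= 0.5 * (cos_t**2 + 1 / xx)
        accept = np.where(branch1, acc1, acc2)
        take = idx[accept]
        x[take] = xx[accept]
        done[take] = True
    cos_theta = 1 - (x - 1) / alpha
    return e_kev / x, cos_theta


def _rotate(directions: np.ndarray, cos_theta: np.ndarray, rng) -> np.ndarray:
    """Rotate each unit vector by theta with uniform random azimuth."""
    n = directions.shape[0]
    phi = 2.0 * np.pi * rng.random(n)
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    d = directions
    # orthonormal frame (u, v, d); avoid degeneracy near the poles
    helper = np.where(np.abs(d[:, 2:3]) < 0.99,
                      np.tile([0.0, 0.0, 1.0], (n, 1)),
                      np.tile([1.0, 0.0, 0.0], (n, 1)))
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    new = (d * cos_theta[:, None]
           + u * (sin_theta * np.cos(phi))[:, None]
           + v * (sin_theta * np.sin(phi))[:, None])
    return new / np.linalg.norm(new, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# grid marching
# ---------------------------------------------------------------------------


class _GridWalker:
    """Exact ray stepping through the voxel lattice (continuous positions in mm)."""

    def __init__(self, grid: VoxelGrid):
        self.dims = np.array(grid.dims)
        self.spacing = np.array(grid.spacing_mm)
        self.origin = np.array(grid.origin_mm)
        self.eps_mm = 1e-9 * float(self.spacing.min())

    def voxel_of(self, pos: np.ndarray) -> np.ndarray:
        u = (pos - self.origin) / self.spacing + 0.5
        return np.floor(u).astype(np.int64)

    def inside(self, ivox: np.ndarray) -> np.ndarray:
        return np.all((ivox >= 0) & (ivox < self.dims), axis=1)

    def distance_to_boundary(self, pos: np.ndarray, ivox: np.ndarray,
                             dirs: np.ndarray) -> np.ndarray:
        """Distance (mm) along dirs to the first voxel face, per ray."""
        lo = self.origin + (ivox - 0.5) * self.spacing
        hi = lo + self.spacing
        with np.errstate(divide="ignore", invalid="ignore"):
            t_hi = (hi - pos) / dirs
            t_lo = (lo - pos) / dirs
        t = np.where(dirs > 0, t_hi, np.where(dirs < 0, t_lo, np.inf))
        return np.maximum(t.min(axis=1), 0.0)


def _flat(ivox: np.ndarray, dims: np.ndarray) -> np.ndarray:
    return (ivox[:, 0] * dims[1] + ivox[:, 1]) * dims[2] + ivox[:, 2]


def _transport_photons(walker: _GridWalker, rho_flat: np.ndarray,
                       nuclide: NuclideData, cutoff_kev: float,
                       pos: np.ndarray, dirs: np.ndarray, e_kev: np.ndarray,
                       rng, tally: np.ndarray) -> float:
    """Track photons to absorption, cutoff, or grid escape.

    Deposits energy into ``tally`` (flat keV array); returns escaped keV.
    """
    escaped = 0.0
    max_generations = 200
    for _ in range(max_generations):
        n = e_kev.size
        if n == 0:
            break
        tau_left = -np.log(rng.random(n))
        mu_pe_w = nuclide.mu_photoelectric(e_kev)
        mu_in_w = nuclide.mu_incoherent(e_kev)
        mu_w = (mu_pe_w + mu_in_w) / 10.0  # cm^2/g -> mm^2/g per mm at rho in g/cm^3

        ivox = walker.voxel_of(pos)
        alive = walker.inside(ivox)
        escaped += float(e_kev[~alive].sum())
        pos, dirs, e_kev = pos[alive], dirs[alive], e_kev[alive]
        tau_left, mu_w = tau_left[alive], mu_w[alive]
        mu_pe_w, mu_in_w = mu_pe_w[alive], mu_in_w[alive]
        ivox = ivox[alive]

        interacted = np.zeros(e_kev.size, dtype=bool)
        int_voxel = np.zeros(e_kev.size, dtype=np.int64)
        active = np.ones(e_kev.size, dtype=bool)
        # march rays voxel by voxel until every photon interacts or escapes
        while active.any():
            ai = np.flatnonzero(active)
            iv = ivox[ai]
            fl = _flat(iv, walker.dims)
            mu_lin = mu_w[ai] * rho_flat[fl]  # 1/mm
            t_bnd = walker.distance_to_boundary(pos[ai], iv, dirs[ai])
            dtau = mu_lin * t_bnd
            hit = tau_left[ai] <= dtau
            # interaction inside the current voxel
            hit_idx = ai[hit]
            if hit_idx.size:
                s = tau_left[hit_idx] / mu_lin[hit]
                pos[hit_idx] += dirs[hit_idx] * s[:, None]
                interacted[hit_idx] = True
                int_voxel[hit_idx] = fl[hit]
                active[hit_idx] = False
            # the rest cross into the next voxel
            go_idx = ai[~hit]
            if go_idx.size:
                tau_left[go_idx] -= dtau[~hit]
                pos[go_idx] += dirs[go_idx] * (t_bnd[~hit] + walker.eps_mm)[:, None]
                iv_new = walker.voxel_of(pos[go_idx])
                ivox[go_idx] = iv_new
                out = ~walker.inside(iv_new)
                if out.any():
                    lost = go_idx[out]
                    escaped += float(e_kev[lost].sum())
                    active[lost] = False

        # resolve interactions
        ii = np.flatnonzero(interacted)
        if ii.size == 0:
            break
        fl = int_voxel[ii]
        e_int = e_kev[ii]
        p_pe = mu_pe_w[ii] / (mu_pe_w[ii] + mu_in_w[ii])
        photo = rng.random(ii.size) < p_pe
        if photo.any():
            np.add.at(tally, fl[photo], e_int[photo])
        compt = ~photo
        if not compt.any():
            break
        ci = ii[compt]
        e_new, cos_t = _kahn_compton(rng, e_kev[ci])
        np.add.at(tally, fl[compt], e_kev[ci] - e_new)  # recoil electron, local
        below = e_new < cutoff_kev
        if below.any():
            np.add.at(tally, fl[compt][below], e_new[below])
        keep = ~below
        ki = ci[keep]
        if ki.size == 0:
            break
        new_dirs = _rotate(dirs[ki], cos_t[keep], rng)
        pos, dirs, e_kev = pos[ki].copy(), new_dirs, e_new[keep]
    return escaped


def _transport_betas(walker: _GridWalker, rho_flat: np.ndarray,
                     nuclide: NuclideData,
                     pos: np.ndarray, e_kev: np.ndarray,
                     rng, tally: np.ndarray) -> float:
    """Straight-line CSDA slowing-down with uniform energy loss per
    water-equivalent path; returns escaped keV."""
    dirs = _isotropic_directions(rng, e_kev.size)
    range_weq = nuclide.csda_range_mm(e_kev)  # mm at unit density
    left_weq = range_weq.copy()
    e_per_weq = e_kev / range_weq
    ivox = walker.voxel_of(pos)
    alive = walker.inside(ivox)
    escaped = float(e_kev[~alive].sum())
    pos, dirs, ivox = pos[alive], dirs[alive], ivox[alive]
    left_weq, e_per_weq = left_weq[alive], e_per_weq[alive]

    active = np.ones(left_weq.size, dtype=bool)
    while active.any():
        ai = np.flatnonzero(active)
        iv = ivox[ai]
        fl = _flat(iv, walker.dims)
        rho = rho_flat[fl]
        t_bnd = walker.distance_to_boundary(pos[ai], iv, dirs[ai])
        weq_seg = rho * t_bnd
        stop = left_weq[ai] <= weq_seg
        stop_idx = ai[stop]
        if stop_idx.size:
            np.add.at(tally, fl[stop], e_per_weq[stop_idx] * left_weq[stop_idx])
            active[stop_idx] = False
        go_idx = ai[~stop]
        if go_idx.size:
            np.add.at(tally, fl[~stop], e_per_weq[go_idx] * weq_seg[~stop])
            left_weq[go_idx] -= weq_seg[~stop]
            pos[go_idx] += dirs[go_idx] * (t_bnd[~stop] + walker.eps_mm)[:, None]
            iv_new = walker.voxel_of(pos[go_idx])
            ivox[go_idx] = iv_new
            out = ~walker.inside(iv_new)
            if out.any():
                lost = go_idx[out]
                escaped += float(e_per_weq[lost] * left_weq[lost])
                active[lost] = False
    return escaped


# ---------------------------------------------------------------------------
# main engine
# ---------------------------------------------------------------------------


def run_mc(source: SourceMap, density: DensityMap, nuclide: NuclideData,
           cfg: TransportConfig) -> DoseMap:
    """Monte Carlo dose from a voxel source map on a density grid.

    Per history: emission voxel sampled from the source probabilities
    with a uniform position inside the voxel; one beta per decay with
    branch energy from the spectrum; each photon line emitted with its
    yield.  Identical (seed, config, inputs) give bit-identical output.
    """
    check_same_grid(source, density)
    grid = source.grid
    nvox = int(np.prod(grid.dims))
    shape = tuple(grid.dims)

    if source.total_decays == 0:
        z = np.zeros(shape)
        return DoseMap(grid=grid, dose_gy=z, rel_se=z.copy(),
                       histories=cfg.n_histories, seed=cfg.seed)

    probs = source.probabilities.ravel()
    if probs.sum() <= 0:
        raise ValueError("source has zero total probability")
    cdf = np.cumsum(probs)
    cdf /= cdf[-1]

    rho_flat = (np.ones(nvox) if cfg.uniform_density
                else density.values.ravel().copy())
    walker = _GridWalker(grid)
    spacing = np.array(grid.spacing_mm)
    origin = np.array(grid.origin_mm)

    be = np.array([e for e, _ in nuclide.beta_spectrum])
    bp = np.array([p for _, p in nuclide.beta_spectrum])

    voxel_mass_kg = rho_flat * grid.voxel_volume_ml * 1e-3  # mL * g/cm^3 -> g -> kg

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.batches)
    n_per = np.full(cfg.batches, cfg.n_histories // cfg.batches)
    n_per[: cfg.n_histories % cfg.batches] += 1

    batch_dose = np.zeros((cfg.batches, nvox))
    emitted_total = 0.0
    deposited_total = 0.0
    escaped_total = 0.0

    for b in range(cfg.batches):
        nb = int(n_per[b])
        if nb == 0:
            continue
        rng = np.random.default_rng(seeds[b])
        tally = np.zeros(nvox)

        vox = np.searchsorted(cdf, rng.random(nb), side="right")
        iv = np.stack(np.unravel_index(vox, shape), axis=1)
        pos = origin + (iv + rng.random((nb, 3)) - 0.5) * spacing

        e_beta = _sample_discrete(rng, be, bp, nb)
        emitted = float(e_beta.sum())
        if cfg.beta_mode == "local":
            np.add.at(tally, vox, e_beta)
            esc = 0.0
        else:
            esc = _transport_betas(walker, rho_flat, nuclide, pos.copy(),
                                   e_beta, rng, tally)

        if cfg.photons_on:
            for e_line, yield_ in nuclide.photon_lines:
                emit = rng.random(nb) < yield_
                ng = int(emit.sum())
                if ng == 0:
                    continue
                emitted += e_line * ng
                dirs = _isotropic_directions(rng, ng)
                esc += _transport_photons(
                    walker, rho_flat, nuclide, cfg.photon_cutoff_kev,
                    pos[emit].copy(), dirs, np.full(ng, float(e_line)),
                    rng, tally)

        emitted_total += emitted
        deposited_total += float(tally.sum())
        escaped_total += esc
        batch_dose[b] = tally * KEV_TO_J * (source.total_decays / nb) / voxel_mass_kg

    dose = batch_dose.mean(axis=0)
    se = batch_dose.std(axis=0, ddof=1) / np.sqrt(cfg.batches)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_se = np.where(dose > 0, se / np.where(dose > 0, dose, 1.0), 0.0)

    out = DoseMap(
        grid=grid,
        dose_gy=dose.reshape(shape),
        rel_se=rel_se.reshape(shape),
        histories=cfg.n_histories,
        seed=cfg.seed,
        energy_emitted_kev=emitted_total,
        energy_deposited_kev=deposited_total,
        meta={
            "batches": cfg.batches,
            "beta_mode": cfg.beta_mode,
            "photons_on": cfg.photons_on,
            "uniform_density": cfg.uniform_density,
            "escaped_kev": escaped_total,
        },
    )
    if cfg.keep_batches:
        out.meta["batch_dose_gy"] = batch_dose
    return out


def region_mean_se(dose_map: DoseMap, flat_indices: np.ndarray) -> tuple[float, float]:
    """Mean dose over a voxel region with its batch standard error.

    Requires run_mc with ``keep_batches=True``; the SE is the standard
    error across batch-wise region means, which correctly accounts for
    intra-batch correlation between voxels.
    """
    batch = dose_map.meta.get("batch_dose_gy")
    if batch is None:
        raise ValueError("run_mc must be called with keep_batches=True")
    means = batch[:, flat_indices].mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1) / np.sqrt(means.size))


def equilibrium_dose(decays_per_voxel: float, nuclide: NuclideData,
                     grid: VoxelGrid, density_g_cm3: float = 1.0,
                     absorbed_fraction: float = 1.0,
                     include_photons: bool = True) -> float:
    """Closed-form dose in an infinite uniform self-irradiating medium.

    Every voxel absorbs exactly what it emits: decays * energy per decay
    / voxel mass.  ``absorbed_fraction`` scales the photon component for
    finite-geometry comparisons; betas are always fully absorbed.
    """
    if decays_per_voxel < 0:
        raise ValueError("decays must be >= 0")
    e_kev = nuclide.mean_beta_energy_kev
    if include_photons:
        e_kev += absorbed_fraction * nuclide.photon_energy_per_decay_kev
    mass_kg = density_g_cm3 * grid.voxel_volume_ml * 1e-3
    return decays_per_voxel * e_kev * KEV_TO_J / mass_kg


def point_kernel(nuclide: NuclideData, cfg: TransportConfig,
                 spacing_mm=(4.79, 4.79, 4.79), halfsize: int = 12) -> np.ndarray:
    """Energy-deposition kernel (keV per decay per voxel) for a point-like
    (single-voxel) source in uniform water, computed by the MC engine."""
    n = 2 * halfsize + 1
    grid = VoxelGrid(dims=(n, n, n), spacing_mm=tuple(spacing_mm))
    probs = np.zeros((n, n, n))
    probs[halfsize, halfsize, halfsize] = 1.0
    src = SourceMap(grid=grid, probabilities=probs, total_decays=1.0)
    dens = DensityMap(grid=grid, values=np.ones((n, n, n)))
    dm = run_mc(src, dens, nuclide, cfg)
    mass_kg = grid.voxel_volume_ml * 1e-3
    return dm.dose_gy * mass_kg / KEV_TO_J  # Gy -> keV per decay


def kernel_dose(tia_or_source, nuclide: NuclideData, cfg: TransportConfig,
                kernel: np.ndarray | None = None, halfsize: int = 12,
                density: DensityMap | None = None) -> DoseMap:
    """Dose by convolving absolute voxel decays with a point kernel.

    Valid only for (assumed) uniform unit-density media; supplying a
    non-uniform density map is an error.  Linear in the source by
    construction.
    """
    if density is not None and np.ptp(density.values) > 1e-12:
        raise ValueError("kernel convolution assumes a uniform density map")
    if isinstance(tia_or_source, SourceMap):
        decays = tia_or_source.probabilities * tia_or_source.total_decays
        grid = tia_or_source.grid
    else:
        decays = np.asarray(tia_or_source.voxel_decays, dtype=np.float64)
        grid = tia_or_source.grid
    if kernel is None:
        kernel = point_kernel(nuclide, cfg, spacing_mm=grid.spacing_mm,
                              halfsize=halfsize)
    mass_kg = grid.voxel_volume_ml * 1e-3
    dose = fftconvolve(decays, kernel, mode="same") * KEV_TO_J / mass_kg
    dose = np.maximum(dose, 0.0)  # FFT round-off can leave tiny negatives
    return DoseMap(grid=grid, dose_gy=dose, rel_se=np.zeros_like(dose),
                   histories=cfg.n_histories, seed=cfg.seed,
                   meta={"method": "kernel"})
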