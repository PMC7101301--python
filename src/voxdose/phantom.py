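"""Digital phantom and SPECT-series simulator.

Builds ellipsoidal/spherical structures on a voxel grid, each with its
own initial activity concentration and mono-exponential washout time
constant, plus a Hounsfield-unit map for density conversion.  The
simulator emulates a reconstructed quantitative SPECT series: Gaussian
PSF blur followed by signal-proportional Gaussian noise (a surrogate
for reconstructed-image noise; there is no projection/reconstruction
stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ActivitySeries, ActivityVolume, RoiMask, VoxelGrid

DEFAULT_TIMES_H = (4.0, 24.0, 48.0, 72.0)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SOFT_TISSUE_HU = 0.0
LUNG_HU = -700.0
BONE_HU = 700.0


@dataclass(frozen=True)
class Structure:
    """One phantom structure: an ellipsoid with washout kinetics.

    radii_mm may be a scalar (sphere) or a 3-tuple.  ``a0_kbq_ml`` is the
    activity concentration at t=0 and ``tau_h`` the effective washout
    time constant.
    """

    name: str
    category: str          # "kidney" | "spleen" | lesion subtype
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    a0_kbq_ml: float
    tau_h: float
    hu: float = SOFT_TISSUE_HU

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("radii must be positive")
        if self.a0_kbq_ml < 0:
            raise ValueError("a0 must be >= 0")
        if self.tau_h <= 0:
            raise ValueError("tau must be positive")


def sphere(name: str, category: str, center_mm, radius_mm: float,
           a0_kbq_ml: float, tau_h: float, hu: float = SOFT_TISSUE_HU) -> Structure:
    return Structure(name=name, category=category, center_mm=tuple(center_mm),
                     radii_mm=(radius_mm,) * 3, a0_kbq_ml=a0_kbq_ml,
                     tau_h=tau_h, hu=hu)


@dataclass
class PhantomSpec:
    grid: VoxelGrid
    structures: list[Structure]
    background_hu: float = SOFT_TISSUE_HU
    times_h: tuple[float, ...] = DEFAULT_TIMES_H


@dataclass
class PhantomTruth:
    """Ground truth: mask, kinetics parameters, HU map, noise-free series."""

    spec: PhantomSpec
    mask: RoiMask
    hu: np.ndarray
    series: ActivitySeries           # noise-free
    params: dict[int, dict] = field(default_factory=dict)  # label -> truth record

    @property
    def grid(self) -> VoxelGrid:
        return self.spec.grid


def build_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize structures by voxel-center inclusion and assemble truth.

    Overlaps resolve to the earlier-listed structure; a warning reports
    how many voxels each later structure lost.
    """
    grid = spec.grid
    shape = tuple(grid.dims)
    labels = np.zeros(shape, dtype=np.int32)
    hu = np.full(shape, spec.background_hu, dtype=np.float64)
    names: dict[int, tuple[str, str]] = {}
    params: dict[int, dict] = {}

    cx = grid.voxel_centers_mm(0)[:, None, None]
    cy = grid.voxel_centers_mm(1)[None, :, None]
    cz = grid.voxel_centers_mm(2)[None, None, :]

    claimed = []
    for k, st in enumerate(spec.structures, start=1):
        d2 = (((cx - st.center_mm[0]) / st.radii_mm[0]) ** 2
              + ((cy - st.center_mm[1]) / st.radii_mm[1]) ** 2
              + ((cz - st.center_mm[2]) / st.radii_mm[2]) ** 2)
        inside = d2 <= 1.0
        if not inside.any():
            raise ValueError(f"structure {st.name!r} lies entirely outside the grid")
        overlap = inside & (labels > 0)
        n_lost = int(overlap.sum())
        if n_lost:
            claimed.append((st.name, n_lost))
        sel = inside & (labels == 0)
        labels[sel] = k
        hu[sel] = st.hu
        names[k] = (st.name, st.category)
        params[k] = {
            "a0_kbq_ml": st.a0_kbq_ml,
            "tau_h": st.tau_h,
            "voxel_count": int(sel.sum()),
            "volume_ml": float(sel.sum()) * grid.voxel_volume_ml,
        }
    if claimed:
        warnings.warn("overlapping structures lost voxels to earlier ones: "
                      + ", ".join(f"{n}={c}" for n, c in claimed), stacklevel=2)

    mask = RoiMask(grid=grid, labels=labels, names=names)
    vols = []
    for t in spec.times_h:
        frame = np.zeros(shape)
        for k, p in params.items():
            frame[labels == k] = p["a0_kbq_ml"] * np.exp(-t / p["tau_h"])
        vols.append(ActivityVolume(grid=grid, values=frame, time_h=float(t)))
    series = ActivitySeries(volumes=vols)
    return PhantomTruth(spec=spec, mask=mask, hu=hu, series=series, params=params)


def simulate_series(truth: PhantomTruth,
                    times_h=None,
                    psf_fwhm_mm: float = 0.0,
                    noise_scale: float = 0.0,
                    seed: int = 0) -> ActivitySeries:
    """Blur + noise model for a reconstructed quantitative SPECT series.

    Each noise-free frame is blurred with an isotropic Gaussian PSF
    (zero-padded borders), then perturbed with independent Gaussian noise
    of standard deviation noise_scale * sqrt(value); negative results are
    clipped to zero and their count recorded on the returned series as
    ``clipped_voxels``.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    grid = truth.grid
    if times_h is None:
        times_h = truth.spec.times_h
    times_h = tuple(float(t) for t in times_h)
    if any(t2 <= t1 for t1, t2 in zip(times_h, times_h[1:])):
        raise ValueError("times must be strictly increasing")

    labels = truth.mask.labels
    rng = np.random.default_rng(seed)
    sigma_vox = [psf_fwhm_mm * FWHM_TO_SIGMA / s for s in grid.spacing_mm]

    clipped = 0
    vols = []
    for t in times_h:
        frame = np.zeros(tuple(grid.dims))
        for k, p in truth.params.items():
            frame[labels == k] = p["a0_kbq_ml"] * np.exp(-t / p["tau_h"])
        if psf_fwhm_mm > 0:
            frame = ndimage.gaussian_filter(frame, sigma=sigma_vox, mode="constant")
        if noise_scale > 0:
            frame = frame + rng.standard_normal(frame.shape) * noise_scale * np.sqrt(frame)
            neg = frame < 0
            clipped += int(neg.sum())
            frame[neg] = 0.0
        vols.append(ActivityVolume(grid=grid, values=frame, time_h=t))
    series = ActivitySeries(volumes=vols)
    series.clipped_voxels = clipped  # type: ignore[attr-defined]
    return series


def density_from_truth(truth: PhantomTruth):
    """Convert the phantom HU map to a mass-density map (g/cm^3)."""
    from .mc_dose import hu_to_density
    return hu_to_density(truth.hu, truth.grid)
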