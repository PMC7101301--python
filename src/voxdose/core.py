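"""Shared voxel-grid conventions and volume/mask containers.

All volumes in a pipeline run live on one common isotropic-or-not voxel
grid; nothing in this package resamples implicitly.  Voxel indices are
0-based, world coordinates are voxel-center positions in mm, and the
default grid spacing (4.79 mm isotropic) matches quantitative SPECT
reconstructions downsampled from CT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

DEFAULT_SPACING_MM = (4.79, 4.79, 4.79)

GRID_ATOL_MM = 1e-6


class GridMismatchError(ValueError):
    """Two gridded objects do not share dims/spacing."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D voxel lattice.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis; all >= 1.
    spacing_mm : tuple of float
        Voxel edge length per axis in mm; all > 0.
    origin_mm : tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3); product of spacings / 1000."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.dims[axis])

    def matches(self, other: "VoxelGrid", atol_mm: float = GRID_ATOL_MM) -> bool:
        return self.dims == other.dims and all(
            abs(a - b) <= atol_mm for a, b in zip(self.spacing_mm, other.spacing_mm)
        )


def check_same_grid(a, b, atol_mm: float = GRID_ATOL_MM) -> None:
    """Raise GridMismatchError naming the first differing axis.

    Accepts any pair of objects carrying a ``grid`` attribute, or bare
    VoxelGrid instances.
    """
    ga = a if isinstance(a, VoxelGrid) else a.grid
    gb = b if isinstance(b, VoxelGrid) else b.grid
    for ax in range(3):
        if ga.dims[ax] != gb.dims[ax]:
            raise GridMismatchError(
                f"grid dims differ on axis {ax + 1}: {ga.dims[ax]} vs {gb.dims[ax]}"
            )
    for ax in range(3):
        if abs(ga.spacing_mm[ax] - gb.spacing_mm[ax]) > atol_mm:
            raise GridMismatchError(
                f"grid spacing differs on axis {ax + 1}: "
                f"{ga.spacing_mm[ax]} vs {gb.spacing_mm[ax]} mm"
            )


@dataclass
class ActivityVolume:
    """One calibrated activity image (kBq/mL) at a time point.

    ``time_h`` is hours post injection.  Negative concentrations are not
    physical; they may appear after noise and should be clipped by the
    producer (the simulator counts them).
    """

    grid: VoxelGrid
    values: np.ndarray
    time_h: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")


@dataclass
class ActivitySeries:
    """Time-ordered activity volumes on a common grid (>= 2 frames)."""

    volumes: list[ActivityVolume]

    def __post_init__(self) -> None:
        if len(self.volumes) < 2:
            raise ValueError("an activity series needs at least 2 time points")
        times = [v.time_h for v in self.volumes]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"times must be strictly increasing, got {times}")
        for v in self.volumes[1:]:
            check_same_grid(self.volumes[0], v)

    @property
    def grid(self) -> VoxelGrid:
        return self.volumes[0].grid

    @property
    def times_h(self) -> np.ndarray:
        return np.array([v.time_h for v in self.volumes])

    def stack(self) -> np.ndarray:
        """(T, nx, ny, nz) array of concentrations."""
        return np.stack([v.values for v in self.volumes])


@dataclass
class RoiMask:
    """Integer label volume (0 = background) with a label -> (name, category) map.

    Categories distinguish organs-at-risk from tumor lesions; lesion
    subtypes (liver, lymph node, bone, ...) ride in the category string.
    """

    grid: VoxelGrid
    labels: np.ndarray
    names: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        if self.labels.shape != tuple(self.grid.dims):
            raise ValueError("mask shape does not match grid dims")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    def voxel_indices(self, label: int) -> np.ndarray:
        """Flat indices of voxels carrying ``label``; errors if absent."""
        if label not in self.names:
            raise KeyError(f"label {label} not defined in mask")
        idx = np.flatnonzero(self.labels.ravel() == label)
        if idx.size == 0:
            raise ValueError(f"label {label} ({self.names[label][0]}) has no voxels")
        return idx

    def labels_by_category(self, category: str) -> list[int]:
        return sorted(k for k, (_, cat) in self.names.items() if cat == category)


# ---------------------------------------------------------------------------
# NIfTI I/O.  The affine encodes spacing on the diagonal and the origin in
# the translation column; we write RAS+ with no rotation (all volumes in a
# run are co-registered by construction).
# ---------------------------------------------------------------------------


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing_mm) + [1.0])
    aff[:3, 3] = grid.origin_mm
    return aff


def _grid_from_nifti(img: nib.Nifti1Image, path) -> VoxelGrid:
    if img.ndim != 3:
        raise ValueError(f"{path}: not a 3-D volume (ndim={img.ndim})")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid spacing metadata {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VoxelGrid(dims=tuple(img.shape), spacing_mm=tuple(float(z) for z in zooms),
                     origin_mm=origin)


def write_volume(path, values: np.ndarray, grid: VoxelGrid) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(grid))
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(path))


def read_volume(path, time_h: float | None = None):
    """Read a 3-D NIfTI volume.

    Returns an ActivityVolume when ``time_h`` is given, else a bare
    ``(values, grid)`` pair (e.g. for HU maps).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_nifti(img, path)
    values = np.asarray(img.dataobj, dtype=np.float64)
    if time_h is None:
        return values, grid
    return ActivityVolume(grid=grid, values=values, time_h=time_h)


def write_series(directory, series: ActivitySeries, prefix: str = "activity") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for vol in series.volumes:
        p = directory / f"{prefix}_t{vol.time_h:06.1f}h.nii.gz"
        write_volume(p, vol.values, vol.grid)
        paths.append(p)
    return paths


def read_series(paths, times_h) -> ActivitySeries:
    vols = [read_volume(p, time_h=t) for p, t in zip(paths, times_h)]
    return ActivitySeries(volumes=vols)


def write_mask(path, mask: RoiMask) -> None:
    """Label image as int16 NIfTI plus a sidecar JSON label map."""
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.grid))
    img.header.set_zooms(mask.grid.spacing_mm)
    nib.save(img, str(path))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json")
    sidecar.write_text(json.dumps(
        {str(k): {"name": n, "category": c} for k, (n, c) in mask.names.items()},
        indent=2))


def read_mask(path) -> RoiMask:
    img = nib.load(str(path))
    grid = _grid_from_nifti(img, path)
    labels = np.asarray(img.dataobj).astype(np.int64)
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing label sidecar {sidecar}")
    raw = json.loads(sidecar.read_text())
    names = {int(k): (v["name"], v["category"]) for k, v in raw.items()}
    return RoiMask(grid=grid, labels=labels, names=names)
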