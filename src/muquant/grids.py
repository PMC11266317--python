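"""Voxel grids and typed volumes (labels, HU, mu, ACF, activity).

Conventions
-----------
Arrays are indexed ``values[ix, iy, iz]`` with axial slices in the xy plane.
The world frame is right-handed, in millimetres; ``origin`` is the world
position of the *center* of voxel ``(0, 0, 0)``, so voxel ``i`` is centered at
``origin + i * spacing``.  Volumes round-trip through NIfTI with a diagonal
affine built from spacing and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "Volume",
    "LabelVolume",
    "HUVolume",
    "MuMap",
    "ACFVolume",
    "ActivityVolume",
    "resample_trilinear",
    "save_volume",
    "load_volume",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice: shape (voxels), spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid grid spacing {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate meshes of all voxel centers."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points, shape (..., 3)."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.array(self.origin)) / np.array(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """World bounding box of the voxel *edges* (lo, hi)."""
        lo = np.array(self.origin) - 0.5 * np.array(self.spacing)
        hi = lo + np.array(self.shape) * np.array(self.spacing)
        return lo, hi


@dataclass
class Volume:
    """A voxel grid plus a value per voxel."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def sample(self, points_mm: np.ndarray, outside: float = 0.0) -> np.ndarray:
        """Trilinear sample at world points (outside the grid -> ``outside``)."""
        idx = self.grid.world_to_index(points_mm)
        return ndimage.map_coordinates(
            self.values.astype(float), idx.reshape(-1, 3).T, order=1, mode="constant",
            cval=outside,
        ).reshape(np.asarray(points_mm).shape[:-1])


@dataclass
class LabelVolume(Volume):
    """Integer material labels with a label -> material-name legend."""

    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.int32)
        present = set(np.unique(self.values).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels without legend entry: {sorted(missing)}")


@dataclass
class HUVolume(Volume):
    """CT image in Hounsfield units (water 0, air -1000)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.min(self.values) < -1024.0:
            raise ValueError("HU values below -1024")


@dataclass
class MuMap(Volume):
    """Linear attenuation coefficients (cm^-1) at a reference energy."""

    energy_kev: float = 208.4

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.min(self.values) < 0:
            raise ValueError("negative attenuation coefficients")


@dataclass
class ACFVolume(Volume):
    """Chang attenuation-correction factors (dimensionless, >= 1)."""

    provenance: str = "theoretical"  # or "measured"
    angles: int = 0


@dataclass
class ActivityVolume(Volume):
    """Activity concentration (MBq/mL) plus nominal per-source activities."""

    nominal_mbq: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.min(self.values) < 0:
            raise ValueError("negative activity")

    def total_mbq(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume_mm3 / 1000.0)


def resample_trilinear(
    volume: Volume, target: VoxelGrid, outside: str = "error", fill: float = 0.0
) -> np.ndarray:
    """Trilinear resampling of ``volume`` onto ``target`` voxel centers.

    ``outside='error'`` requires every target center to fall inside the source
    voxel-edge bounding box; ``outside='fill'`` uses ``fill`` beyond it.
    """
    tx, ty, tz = (target.axis_centers(a) for a in range(3))
    pts = np.stack(np.meshgrid(tx, ty, tz, indexing="ij"), axis=-1)
    lo, hi = volume.grid.bounds_mm()
    inside = np.all((pts >= lo) & (pts <= hi), axis=-1)
    if outside == "error" and not inside.all():
        raise ValueError("target grid extends outside the source volume extent")
    idx = volume.grid.world_to_index(pts)
    # 'nearest' handles the half-voxel shell between edge centers and edges.
    out = ndimage.map_coordinates(
        volume.values.astype(float), idx.reshape(-1, 3).T, order=1, mode="nearest"
    ).reshape(target.shape)
    if outside == "fill":
        out = np.where(inside, out, fill)
    return out


def save_volume(volume: Volume, path: str) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz)."""
    import nibabel as nib

    affine = np.diag(list(volume.grid.spacing) + [1.0])
    affine[:3, 3] = volume.grid.origin
    img = nib.Nifti1Image(np.asarray(volume.values), affine)
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, path)


def load_volume(path: str) -> Volume:
    """Read a NIfTI volume written by :func:`save_volume`."""
    import nibabel as nib

    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError("expected a 3-D volume")
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    grid = VoxelGrid(tuple(img.shape), spacing, origin)
    return Volume(grid, np.asarray(img.dataobj))


def _replace_values(vol: Volume, values: np.ndarray, **extra):
    return replace(vol, values=values, **extra)
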