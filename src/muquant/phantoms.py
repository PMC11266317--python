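"""Digital phantom generation.

Two phantoms are emulated:

* an electron-density phantom — an elliptical plastic-water body (26 cm
  anterior-posterior by 32 cm lateral) carrying 17 cylindrical inserts of 9
  tissue-equivalent materials on an inner and an outer ring, plus an
  insert-free homogeneous section used for noise analysis;
* a quantification phantom — a water-filled NEMA-style body holding four
  attenuation cylinders (polystyrene foam, PTFE, polyamide, polypropylene),
  each with an axial bore carrying a syringe source (1 mL or 10 mL) of
  uniform 177Lu activity.

Voxel assignment is by center-point membership, which makes generation
deterministic: the same layout and grid always produce bit-identical labels.
Insert coordinates are configurable defaults (the physical phantom's exact
layout is emulated, not measured); the 1250 mg/cm^3 hydroxyapatite bone
insert appears only once, at the inner (central) position, so the inner ring
holds 9 inserts and the outer ring 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ActivityVolume, LabelVolume, MuMap, VoxelGrid
from .physics import LU177_KEV, MaterialSpec, linear_attenuation

__all__ = [
    "GeometryError",
    "CylinderSpec",
    "InsertLayout",
    "QuantLayout",
    "default_density_layout",
    "default_quant_layout",
    "build_density_phantom",
    "build_quant_phantom",
    "downsample_labels",
    "labels_to_mu",
    "density_phantom_grid",
    "spect_grid",
]


class GeometryError(ValueError):
    """Inconsistent phantom geometry (overlaps, out-of-body inserts...)."""


@dataclass(frozen=True)
class CylinderSpec:
    """Axial cylinder: material name, center (mm, in-plane) and radius (mm)."""

    material: str
    cx: float
    cy: float
    radius: float


@dataclass(frozen=True)
class InsertLayout:
    """Electron-density-phantom geometry (all lengths in mm)."""

    body_half_axes: tuple[float, float] = (160.0, 130.0)  # lateral, AP
    body_z: tuple[float, float] = (6.0, 252.0)
    insert_z: tuple[float, float] = (30.0, 90.0)
    homogeneous_z: tuple[float, float] = (105.0, 245.0)
    inner: tuple[CylinderSpec, ...] = ()
    outer: tuple[CylinderSpec, ...] = ()
    body_material: str = "plastic_water"

    @property
    def inserts(self) -> tuple[CylinderSpec, ...]:
        return self.inner + self.outer

    def validate(self) -> None:
        bx, by = self.body_half_axes
        for a, b in [(self.body_z, None), (self.insert_z, None)]:
            if a[1] <= a[0]:
                raise GeometryError(f"empty z range {a}")
        ins = self.inserts
        for c in ins:
            if (c.cx / (bx - c.radius)) ** 2 + (c.cy / (by - c.radius)) ** 2 > 1.0:
                raise GeometryError(f"insert {c.material} at ({c.cx}, {c.cy}) outside body")
        for i, a in enumerate(ins):
            for b in ins[i + 1:]:
                if np.hypot(a.cx - b.cx, a.cy - b.cy) < a.radius + b.radius:
                    raise GeometryError(f"inserts {a.material} and {b.material} overlap")


_RING_MATERIALS = [
    "lung_inhale", "lung_exhale", "adipose", "breast",
    "muscle", "liver", "bone_200", "bone_800",
]


def default_density_layout(insert_radius: float = 15.0) -> InsertLayout:
    """Default 17-insert layout: 1250 HA bone central, 8 materials per ring."""
    inner = [CylinderSpec("bone_1250", 0.0, 0.0, insert_radius)]
    for k, mat in enumerate(_RING_MATERIALS):
        t = 2 * np.pi * k / 8
        inner.append(CylinderSpec(mat, 60.0 * np.cos(t), 60.0 * np.sin(t), insert_radius))
    outer = []
    for k, mat in enumerate(_RING_MATERIALS):
        t = 2 * np.pi * (k + 0.5) / 8
        outer.append(CylinderSpec(mat, 140.0 * np.cos(t), 110.0 * np.sin(t), insert_radius))
    layout = InsertLayout(inner=tuple(inner), outer=tuple(outer))
    layout.validate()
    return layout


def density_phantom_grid(scale: int = 1) -> VoxelGrid:
    """The study's high-resolution CT grid, optionally decimated by ``scale``."""
    n = 512 // scale
    s = 0.977 * scale
    nz = 86
    # Center the 500 mm transaxial field of view on the phantom axis.
    return VoxelGrid((n, n, nz), (s, s, 3.0), (-(n - 1) * s / 2, -(n - 1) * s / 2, 0.0))


def spect_grid(n: int = 128, nz: int = 55, spacing: float = 4.8) -> VoxelGrid:
    """SPECT/mu-map grid (defaults to 128 x 128 x 55 at 4.8 mm)."""
    return VoxelGrid(
        (n, n, nz), (spacing, spacing, spacing),
        (-(n - 1) * spacing / 2, -(n - 1) * spacing / 2, 0.0),
    )


def _cylinder_mask(grid: VoxelGrid, c: CylinderSpec, z_range: tuple[float, float]) -> np.ndarray:
    x, y, z = grid.center_mesh()
    in_plane = (x - c.cx) ** 2 + (y - c.cy) ** 2 <= c.radius**2
    return in_plane & (z >= z_range[0]) & (z <= z_range[1])


def build_density_phantom(
    layout: InsertLayout | None = None, grid: VoxelGrid | None = None
) -> LabelVolume:
    """Voxelize the electron-density phantom: air 0, body 1, inserts 2..18."""
    layout = layout or default_density_layout()
    grid = grid or density_phantom_grid()
    layout.validate()
    x, y, z = grid.center_mesh()
    bx, by = layout.body_half_axes
    labels = np.zeros(grid.shape, dtype=np.int32)
    body = ((x / bx) ** 2 + (y / by) ** 2 <= 1.0) & (z >= layout.body_z[0]) & (z <= layout.body_z[1])
    labels[body] = 1
    legend = {0: "air", 1: layout.body_material}
    for i, c in enumerate(layout.inserts):
        lab = 2 + i
        labels[_cylinder_mask(grid, c, layout.insert_z)] = lab
        legend[lab] = c.material
    return LabelVolume(grid, labels, legend=legend)


def downsample_labels(src: LabelVolume, target: VoxelGrid) -> LabelVolume:
    """Majority-vote downsampling of a label volume onto a coarser grid.

    Each target voxel takes the most frequent label among the source voxels
    whose centers fall inside it; ties break to the smallest label id.
    Target voxels receiving no source voxel default to label 0 (air).
    """
    if any(t < s for t, s in zip(target.spacing, src.grid.spacing)):
        raise ValueError("target grid must be at least as coarse as the source")
    sx = src.grid.axis_centers(0)
    sy = src.grid.axis_centers(1)
    sz = src.grid.axis_centers(2)
    tidx = [
        np.rint((c - target.origin[a]) / target.spacing[a]).astype(np.int64)
        for a, c in enumerate((sx, sy, sz))
    ]
    if all((t < 0).all() or (t >= n).all() for t, n in zip(tidx, target.shape)):
        raise ValueError("source and target grids do not overlap (misaligned frames)")
    ix, iy, iz = np.meshgrid(*tidx, indexing="ij")
    valid = (
        (ix >= 0) & (ix < target.shape[0])
        & (iy >= 0) & (iy < target.shape[1])
        & (iz >= 0) & (iz < target.shape[2])
    )
    flat = (ix * target.shape[1] + iy) * target.shape[2] + iz
    nlab = int(src.values.max()) + 1
    counts = np.bincount(
        flat[valid] * nlab + src.values[valid],
        minlength=int(np.prod(target.shape)) * nlab,
    ).reshape(-1, nlab)
    # argmax returns the first (= smallest label id) maximum: deterministic ties.
    out = np.where(counts.sum(axis=1) > 0, counts.argmax(axis=1), 0)
    legend = dict(src.legend)
    legend.setdefault(0, "air")
    return LabelVolume(target, out.reshape(target.shape).astype(np.int32), legend=legend)


def labels_to_mu(
    labels: LabelVolume,
    registry: dict[str, MaterialSpec],
    energy_kev: float = LU177_KEV,
) -> MuMap:
    """Substitute each label's material mu(E): the theoretical mu-map."""
    missing = sorted({m for m in labels.legend.values() if m not in registry})
    if missing:
        raise KeyError(f"materials missing from registry: {missing}")
    lut = np.zeros(int(max(labels.legend)) + 1)
    for lab, mat in labels.legend.items():
        lut[lab] = linear_attenuation(registry[mat], energy_kev)
    return MuMap(labels.grid, lut[labels.values], energy_kev=energy_kev)


# ---------------------------------------------------------------------------
# Quantification phantom

#: Syringe source geometries: radius (mm) and nominal volume (mL).
SYRINGES = {"1mL": {"radius": 3.5, "volume_ml": 1.0}, "10mL": {"radius": 8.0, "volume_ml": 10.0}}


@dataclass(frozen=True)
class QuantLayout:
    """NEMA-style quantification phantom geometry (mm)."""

    body_half_axes: tuple[float, float] = (150.0, 110.0)
    body_z: tuple[float, float] = (10.0, 250.0)
    cylinder_z: tuple[float, float] = (40.0, 220.0)
    source_z_center: float = 130.0
    bore_margin: float = 1.5  # bore radius = syringe radius + margin
    cylinders: tuple[CylinderSpec, ...] = (
        CylinderSpec("polystyrene_foam", 49.5, 49.5, 25.0),
        CylinderSpec("ptfe", -49.5, 49.5, 15.0),
        CylinderSpec("polyamide", -49.5, -49.5, 15.0),
        CylinderSpec("polypropylene", 49.5, -49.5, 15.0),
    )


def default_quant_layout() -> QuantLayout:
    return QuantLayout()


def build_quant_phantom(
    source: str,
    grid: VoxelGrid | None = None,
    activities_mbq: dict[str, float] | None = None,
    layout: QuantLayout | None = None,
) -> tuple[LabelVolume, ActivityVolume]:
    """Quantification phantom with four syringe sources.

    ``source`` selects the syringe geometry (``"1mL"`` or ``"10mL"``);
    ``activities_mbq`` maps attenuation-material name to nominal activity
    (default 10 MBq/mL of syringe volume, emulating a shared stock solution).
    Per-source voxel activity is normalised so that the voxelized total
    matches the nominal activity exactly.
    """
    if source not in SYRINGES:
        raise ValueError(f"unknown source geometry {source!r}; options: {sorted(SYRINGES)}")
    layout = layout or default_quant_layout()
    grid = grid or spect_grid()
    syr = SYRINGES[source]
    if activities_mbq is None:
        activities_mbq = {c.material: 10.0 * syr["volume_ml"] for c in layout.cylinders}

    bore_radius = syr["radius"] + layout.bore_margin
    for c in layout.cylinders:
        if bore_radius > c.radius:
            raise GeometryError(
                f"syringe bore (r={bore_radius} mm) larger than {c.material} cylinder"
            )

    x, y, z = grid.center_mesh()
    bx, by = layout.body_half_axes
    labels = np.zeros(grid.shape, dtype=np.int32)
    body = ((x / bx) ** 2 + (y / by) ** 2 <= 1.0) & (z >= layout.body_z[0]) & (z <= layout.body_z[1])
    labels[body] = 1
    legend = {0: "air", 1: "water"}

    length = syr["volume_ml"] * 1000.0 / (np.pi * syr["radius"] ** 2)
    z_lo = layout.source_z_center - length / 2
    z_hi = layout.source_z_center + length / 2

    activity = np.zeros(grid.shape)
    nominal: dict[str, float] = {}
    for i, c in enumerate(layout.cylinders):
        labels[_cylinder_mask(grid, c, layout.cylinder_z)] = 2 + i
        legend[2 + i] = c.material
        bore = CylinderSpec("water", c.cx, c.cy, bore_radius)
        labels[_cylinder_mask(grid, bore, layout.cylinder_z)] = 6 + i
        legend[6 + i] = "water"
        src_mask = _cylinder_mask(grid, CylinderSpec("", c.cx, c.cy, syr["radius"]), (z_lo, z_hi))
        n_vox = int(src_mask.sum())
        if n_vox == 0:
            raise GeometryError(f"syringe in {c.material} covers no voxel centers")
        a = float(activities_mbq.get(c.material, 0.0))
        nominal[c.material] = a
        # Uniform concentration, normalised so the voxel sum is exact.
        activity[src_mask] = a / (n_vox * grid.voxel_volume_mm3 / 1000.0)
    label_vol = LabelVolume(grid, labels, legend=legend)
    act_vol = ActivityVolume(grid, activity, nominal_mbq=nominal)
    return label_vol, act_vol
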