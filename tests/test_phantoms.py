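"""Digital phantom construction, downsampling and mu-map assignment."""

import numpy as np
import pytest

from muquant.grids import VoxelGrid
from muquant.phantoms import (
    CylinderSpec,
    GeometryError,
    InsertLayout,
    build_density_phantom,
    build_quant_phantom,
    default_density_layout,
    density_phantom_grid,
    downsample_labels,
    labels_to_mu,
    spect_grid,
)


@pytest.fixture(scope="module")
def coarse_phantom():
    return build_density_phantom(grid=density_phantom_grid(scale=4))


def test_default_layout_has_17_inserts():
    layout = default_density_layout()
    assert len(layout.inserts) == 17
    assert len(layout.inner) == 9 and len(layout.outer) == 8
    # The 1250 mg/cm^3 HA bone insert appears exactly once.
    mats = [c.material for c in layout.inserts]
    assert mats.count("bone_1250") == 1


def test_density_phantom_19_labels(coarse_phantom):
    labels = np.unique(coarse_phantom.values)
    assert len(labels) == 19  # 17 inserts + plastic water + air
    assert coarse_phantom.legend[0] == "air"
    assert coarse_phantom.legend[1] == "plastic_water"


def test_zero_insert_layout_gives_two_labels():
    layout = InsertLayout()
    vol = build_density_phantom(layout, density_phantom_grid(scale=8))
    assert set(np.unique(vol.values)) == {0, 1}


def test_overlapping_inserts_rejected():
    layout = InsertLayout(
        inner=(CylinderSpec("muscle", 0.0, 0.0, 20.0), CylinderSpec("liver", 25.0, 0.0, 20.0))
    )
    with pytest.raises(GeometryError, match="overlap"):
        build_density_phantom(layout, density_phantom_grid(scale=8))


def test_insert_voxel_volume_matches_cylinder_volume(coarse_phantom):
    # Analytic oracle: each insert is a cylinder of known radius and length;
    # voxelization error is bounded by a one-voxel shell around its surface.
    layout = default_density_layout()
    grid = coarse_phantom.grid
    vv = grid.voxel_volume_mm3
    h = max(grid.spacing)
    for i, c in enumerate(layout.inserts):
        length = layout.insert_z[1] - layout.insert_z[0]
        analytic = np.pi * c.radius**2 * length
        shell = (2 * np.pi * c.radius * length + 2 * np.pi * c.radius**2) * h
        voxels = float((coarse_phantom.values == 2 + i).sum()) * vv
        assert abs(voxels - analytic) <= shell


def test_phantom_generation_is_deterministic():
    g = density_phantom_grid(scale=8)
    a = build_density_phantom(grid=g)
    b = build_density_phantom(grid=g)
    assert np.array_equal(a.values, b.values)


def test_downsample_uniform_and_identity():
    g = VoxelGrid((12, 12, 4), (2.0, 2.0, 2.0))
    from muquant.grids import LabelVolume

    uniform = LabelVolume(g, np.ones(g.shape, dtype=int), legend={0: "air", 1: "water"})
    coarse = downsample_labels(uniform, VoxelGrid((6, 6, 2), (4.0, 4.0, 4.0), (1.0, 1.0, 1.0)))
    assert set(np.unique(coarse.values)) == {1}
    same = downsample_labels(uniform, g)
    assert np.array_equal(same.values, uniform.values)


def test_downsample_majority_matches_bruteforce():
    # 3-insert mini-phantom: brute-force per-target-voxel label counting.
    rng = np.random.default_rng(7)
    src_grid = VoxelGrid((24, 24, 6), (1.0, 1.0, 1.0))
    values = rng.integers(0, 4, size=src_grid.shape)
    from muquant.grids import LabelVolume

    legend = {0: "air", 1: "water", 2: "muscle", 3: "liver"}
    src = LabelVolume(src_grid, values, legend=legend)
    tgt = VoxelGrid((8, 8, 2), (3.0, 3.0, 3.0), (1.0, 1.0, 1.0))
    out = downsample_labels(src, tgt)

    sx, sy, sz = (src_grid.axis_centers(a) for a in range(3))
    expected = np.zeros(tgt.shape, dtype=int)
    for ix in range(tgt.shape[0]):
        for iy in range(tgt.shape[1]):
            for iz in range(tgt.shape[2]):
                counts = np.zeros(4, dtype=int)
                for jx in range(src_grid.shape[0]):
                    for jy in range(src_grid.shape[1]):
                        for jz in range(src_grid.shape[2]):
                            t = [
                                round((sx[jx] - tgt.origin[0]) / tgt.spacing[0]),
                                round((sy[jy] - tgt.origin[1]) / tgt.spacing[1]),
                                round((sz[jz] - tgt.origin[2]) / tgt.spacing[2]),
                            ]
                            if t == [ix, iy, iz]:
                                counts[values[jx, jy, jz]] += 1
                expected[ix, iy, iz] = counts.argmax() if counts.sum() else 0
    assert np.array_equal(out.values, expected)


def test_downsample_requires_coarser_target():
    from muquant.grids import LabelVolume

    g = VoxelGrid((4, 4, 4), (4.0, 4.0, 4.0))
    vol = LabelVolume(g, np.zeros(g.shape, dtype=int), legend={0: "air"})
    with pytest.raises(ValueError):
        downsample_labels(vol, VoxelGrid((8, 8, 8), (2.0, 2.0, 2.0)))
    with pytest.raises(ValueError, match="misaligned|overlap"):
        downsample_labels(vol, VoxelGrid((4, 4, 4), (4.0, 4.0, 4.0), (1e6, 1e6, 1e6)))


def test_labels_to_mu_substitution(registry):
    from muquant.grids import LabelVolume

    g = VoxelGrid((6, 6, 2), (4.0, 4.0, 4.0))
    values = np.zeros(g.shape, dtype=int)
    values[2:4, 2:4, :] = 1
    vol = LabelVolume(g, values, legend={0: "air", 1: "plastic_water"})
    mu = labels_to_mu(vol, registry)
    from muquant.physics import linear_attenuation

    assert np.all(mu.values[values == 1] == linear_attenuation(registry["plastic_water"]))
    assert np.all(mu.values[values == 0] < 2e-4)
    # Number of distinct mu values equals number of distinct labels.
    assert len(np.unique(mu.values)) == len(np.unique(values))


def test_labels_to_mu_missing_material():
    from muquant.grids import LabelVolume

    g = VoxelGrid((2, 2, 2), (4.0, 4.0, 4.0))
    vol = LabelVolume(g, np.zeros(g.shape, dtype=int), legend={0: "unobtainium"})
    with pytest.raises(KeyError, match="unobtainium"):
        labels_to_mu(vol, {})


def test_quant_phantom_activity_normalisation():
    labels, act = build_quant_phantom("10mL", spect_grid(64, 40))
    vv = act.grid.voxel_volume_mm3 / 1000.0
    total = act.values.sum() * vv
    assert total == pytest.approx(sum(act.nominal_mbq.values()), rel=1e-3)
    assert len(act.nominal_mbq) == 4


def test_quant_phantom_1ml_syringe_spans_at_most_two_voxels():
    labels, act = build_quant_phantom("1mL", spect_grid(64, 40))
    # Each source occupies at most 2 columns in each transaxial direction.
    occupied = act.values.sum(axis=2) > 0
    from scipy import ndimage as ndi

    lab, n = ndi.label(occupied)
    assert n == 4
    for k in range(1, n + 1):
        xs, ys = np.where(lab == k)
        assert np.ptp(xs) + 1 <= 2 and np.ptp(ys) + 1 <= 2


def test_quant_phantom_zero_activity_and_bad_geometry():
    labels, act = build_quant_phantom(
        "1mL", spect_grid(64, 40), activities_mbq={}
    )
    assert act.values.sum() == 0.0
    from muquant.phantoms import QuantLayout

    tight = QuantLayout(cylinders=(CylinderSpec("ptfe", 0.0, 0.0, 5.0),))
    with pytest.raises(GeometryError, match="bore"):
        build_quant_phantom("10mL", spect_grid(64, 40), layout=tight)
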