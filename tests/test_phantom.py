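"""Phantom generator: geometry, ground truth, determinism, voxel audits."""

import numpy as np
import pytest

from vtsubstrate.grid import BACKGROUND, BLOOD, HT, NORMAL, SCAR
from vtsubstrate.phantom import (
    PhantomSpec,
    ScarPatch,
    make_activation_map,
    make_eam_export,
    make_label_volume,
)
from vtsubstrate.registration import RigidTransform


def test_plain_slab_geometry_and_truth():
    spec = PhantomSpec(shape_kind="slab", noise_sd=0.0)
    labels, intensity, truth = make_label_volume(spec)
    assert set(np.unique(labels.data)) == {BACKGROUND, BLOOD, NORMAL}
    assert np.allclose(truth.true_thickness_mm, 10.0)
    # blood sits below the wall, background above
    myo_z = labels.world_coords(np.argwhere(labels.data == NORMAL))[:, 2]
    assert myo_z.min() >= 0.0 and myo_z.max() <= 10.0


def test_shell_truth_thickness_constant(shell_phantom):
    _, labels, _, truth = shell_phantom
    assert np.allclose(truth.true_thickness_mm, 10.0)
    r = np.linalg.norm(truth.endo_points, axis=1)
    assert r.min() >= 20.0 - 1e-9 and r.max() < 21.3  # first wall voxel band


def test_scar_patch_by_brute_force_column_audit(slab_phantom):
    """Voxelized transmural fraction audited column-by-column along z."""
    spec, labels, _, _ = slab_phantom
    patch = spec.scar_patches[0]
    h = spec.voxel_spacing_mm
    lab = labels.data
    xs = labels.world_coords(np.stack([np.arange(lab.shape[0]), np.zeros(lab.shape[0]), np.zeros(lab.shape[0])], 1))[:, 0]
    ys = labels.world_coords(np.stack([np.zeros(lab.shape[1]), np.arange(lab.shape[1]), np.zeros(lab.shape[1])], 1))[:, 1]
    audited = []
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            if x**2 + y**2 <= (patch.extent - 2 * h) ** 2:  # patch core columns
                col = lab[i, j, :]
                n_wall = np.sum(np.isin(col, (NORMAL, HT, SCAR)))
                audited.append(np.sum(col == SCAR) / n_wall)
    audited = np.asarray(audited)
    # within one voxel-depth of the requested fraction
    assert np.all(np.abs(audited - patch.transmural_fraction) <= h / 10.0 + 1e-9)


def test_ht_rim_surrounds_scar(slab_phantom):
    spec, labels, _, _ = slab_phantom
    from scipy import ndimage

    scar = labels.data == SCAR
    h = spec.voxel_spacing_mm
    dist = ndimage.distance_transform_edt(~scar, sampling=(h, h, h))
    ht = labels.data == HT
    rim = spec.scar_patches[0].ht_rim_width_mm
    assert ht.any()
    assert dist[ht].max() <= rim + 1e-9
    # myocardium within the rim but outside scar is HT, not normal
    should_be_ht = (labels.data == NORMAL) & (dist <= rim)
    assert not should_be_ht.any()


def test_determinism_bitwise():
    spec = lambda: PhantomSpec(
        shape_kind="spherical_shell",
        scar_patches=[ScarPatch(center=(1, 0, 0), extent=25.0)],
        rng_seed=123,
    )
    l1, i1, t1 = make_label_volume(spec())
    l2, i2, t2 = make_label_volume(spec())
    assert l1.data.tobytes() == l2.data.tobytes()
    assert i1.data.tobytes() == i2.data.tobytes()
    e1 = make_eam_export(t1, RigidTransform.identity(), seed=7)
    e2 = make_eam_export(t2, RigidTransform.identity(), seed=7)
    assert e1.equals(e2)
    m1, _ = make_activation_map(seed=9)
    m2, _ = make_activation_map(seed=9)
    assert np.array_equal(m1.points, m2.points)
    assert np.array_equal(m1.times_ms, m2.times_ms)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(center=(20.0, 20.0), extent=12.0),  # exceeds slab extent
        dict(center=(0.0, 0.0), extent=-1.0),
        dict(center=(0.0, 0.0), extent=5.0, transmural_fraction=1.5),
        dict(center=(0.0, 0.0), extent=5.0, ht_rim_width_mm=-0.1),
    ],
)
def test_invalid_patches_rejected(kwargs):
    with pytest.raises(ValueError):
        PhantomSpec(shape_kind="slab", scar_patches=[ScarPatch(**kwargs)])


def test_eam_export_positions_and_transform():
    spec = PhantomSpec(
        shape_kind="spherical_shell",
        scar_patches=[ScarPatch(center=(1, 0, 0), extent=30.0)],
        noise_sd=0.0,
    )
    _, _, truth = make_label_volume(spec)
    # identity transform, zero noise: points lie exactly on the endo sphere
    df = make_eam_export(truth, None, noise_sd_mm=0.0, seed=0)
    body = df[df.category != "fiducial"][["x", "y", "z"]].to_numpy()
    assert np.allclose(np.linalg.norm(body, axis=1), 20.0, atol=1e-9)
    assert (df.category == "fiducial").sum() >= 4
    assert "apex" in set(df.label)

    # known rotation + translation: the inverse restores positions exactly
    T = RigidTransform.from_axis_angle([0, 0, 1], 15.0, (5.0, -3.0, 2.0))
    df_t = make_eam_export(truth, T, noise_sd_mm=0.0, seed=0)
    moved = df_t[df_t.category != "fiducial"][["x", "y", "z"]].to_numpy()
    assert np.allclose(T.inverse().apply(moved), body, atol=1e-9)
    assert truth.eam_transform is T

    with pytest.raises(ValueError):
        make_eam_export(truth, None, n_diastolic=0, n_normal=0)


def test_eam_diastolic_points_at_scar_border():
    spec = PhantomSpec(
        shape_kind="spherical_shell",
        scar_patches=[ScarPatch(center=(1, 0, 0), extent=30.0)],
        noise_sd=0.0,
    )
    _, _, truth = make_label_volume(spec)
    df = make_eam_export(truth, None, noise_sd_mm=0.0, seed=3, border_band_deg=10.0)
    for cat, lo, hi in (("diastolic", 20.0, 40.0), ("normal", 55.0, 180.0)):
        pos = df[df.category == cat][["x", "y", "z"]].to_numpy()
        ang = np.degrees(
            np.arccos(np.clip(pos[:, 0] / np.linalg.norm(pos, axis=1), -1, 1))
        )
        assert ang.min() >= lo - 1e-9 and ang.max() <= hi + 1e-9


def test_activation_map_construction():
    amap, truth = make_activation_map(block=False, seed=0, jitter_sd_mm=0.0)
    # single planar wavefront: monotone in x, no 15 ms gap between neighbors
    from scipy.spatial import cKDTree

    pairs = cKDTree(amap.points).query_pairs(5.0, output_type="ndarray")
    dt = np.abs(amap.times_ms[pairs[:, 0]] - amap.times_ms[pairs[:, 1]])
    assert dt.max() <= 15.0
    assert truth["block_total_length_mm"] == 0.0

    amap_b, truth_b = make_activation_map(
        block=True, block_offset_ms=40.0, seed=0, jitter_sd_mm=0.0
    )
    assert truth_b["block_total_length_mm"] == pytest.approx(30.0)
    # adjacent cross-line pairs differ by ~the constructed offset
    left = amap_b.points[:, 0] < 0
    pairs = cKDTree(amap_b.points).query_pairs(2.5, output_type="ndarray")
    cross = pairs[left[pairs[:, 0]] != left[pairs[:, 1]]]
    dt = np.abs(amap_b.times_ms[cross[:, 0]] - amap_b.times_ms[cross[:, 1]])
    assert np.all(np.abs(dt - 40.0) < 4.0)
    # ground-truth length equals the polyline arc length
    poly = truth_b["block_polylines"][0]
    arc = np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1))
    assert arc == pytest.approx(truth_b["block_total_length_mm"])


def test_truncated_ellipsoid_builds_connected_wall():
    spec = PhantomSpec(shape_kind="truncated_ellipsoid", noise_sd=0.0)
    labels, _, truth = make_label_volume(spec)
    from scipy import ndimage

    myo = np.isin(labels.data, (NORMAL, HT, SCAR))
    _, n_comp = ndimage.label(myo)
    assert n_comp == 1
    # apex fiducial is the point farthest below the base plane
    assert truth.fiducials["apex"][2] == pytest.approx(
        -spec.ellipsoid_semi_axes_mm[2]
    )
    # grid is truncated at the base plane: no voxels beyond it
    zmax = labels.world_coords(np.argwhere(myo))[:, 2].max()
    assert zmax <= spec.ellipsoid_base_fraction * spec.ellipsoid_semi_axes_mm[2]
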