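"""Rigid registration: Kabsch landmarks, ICP refinement, node mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtsubstrate.registration import (
    RigidTransform,
    icp_refine,
    landmark_align,
    map_points_to_nodes,
)
from vtsubstrate.surface import extract_surface_mesh


@pytest.fixture(scope="module")
def shell_mesh(shell_phantom):
    _, labels, _, _ = shell_phantom
    return extract_surface_mesh(labels, "endo")


def test_transform_group_properties():
    T = RigidTransform.from_axis_angle([1, 2, 3], 37.0, (4.0, -1.0, 2.5))
    pts = np.random.default_rng(0).uniform(-10, 10, size=(50, 3))
    back = T.inverse().apply(T.apply(pts))
    assert np.abs(back - pts).max() < 1e-9
    composed = T.compose(T.inverse())
    assert np.allclose(composed.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(composed.translation, 0.0, atol=1e-12)
    with pytest.raises(ValueError):
        RigidTransform(-np.eye(3), np.zeros(3))  # improper rotation


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    angle=st.floats(min_value=-180, max_value=180),
    ax=st.integers(min_value=0, max_value=2),
)
def test_axis_angle_rotations_orthonormal(angle, ax):
    axis = np.eye(3)[ax]
    T = RigidTransform.from_axis_angle(axis, angle)
    assert np.allclose(T.rotation.T @ T.rotation, np.eye(3), atol=1e-12)
    assert np.linalg.det(T.rotation) == pytest.approx(1.0)


def test_landmark_align_identity_and_recovery():
    fid = np.array([[0, 0, 0], [10, 0, 0], [0, 12, 0], [0, 0, 8]], dtype=float)
    T_id, rms = landmark_align(fid, fid)
    assert rms < 1e-12
    assert np.allclose(T_id.rotation, np.eye(3), atol=1e-12)

    T = RigidTransform.from_axis_angle([0, 0, 1], 30.0, (5.0, -3.0, 2.0))
    rec, rms = landmark_align(fid, T.apply(fid))
    assert rms < 1e-9
    assert np.allclose(rec.rotation, T.inverse().rotation, atol=1e-9)


def test_landmark_align_rejects_reflection():
    fid = np.array([[0, 0, 0], [10, 0, 0], [0, 12, 0], [3, 4, 9]], dtype=float)
    mirrored = fid * np.array([-1.0, 1.0, 1.0])
    T, rms = landmark_align(fid, mirrored)
    assert np.linalg.det(T.rotation) == pytest.approx(1.0)
    assert rms > 0.5  # a proper rotation cannot absorb the reflection


def test_landmark_align_input_validation():
    fid = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
    with pytest.raises(ValueError, match="collinear"):
        landmark_align(fid, fid + 1.0)
    with pytest.raises(ValueError, match="mismatch"):
        landmark_align(fid, fid[:3])
    with pytest.raises(ValueError):
        landmark_align(fid[:2], fid[:2])


def test_icp_recovers_perturbation_of_mesh_samples(shell_mesh):
    mesh = shell_mesh
    rng = np.random.default_rng(21)
    sel = rng.choice(len(mesh.vertices), size=300, replace=False)
    pts = mesh.vertices[sel]
    for trial in range(10):
        T = RigidTransform.from_axis_angle(
            rng.normal(size=3), rng.uniform(0, 30), rng.uniform(-10, 10, 3)
        )
        moved = T.apply(pts)
        # landmark stage: four well-spread surface points as fiducials
        fid_idx = [0, 50, 120, 250]
        init, _ = landmark_align(pts[fid_idx], moved[fid_idx])
        rec, rms, _ = icp_refine(moved, mesh.vertices, mesh.faces, init=init)
        err = np.sqrt(np.mean(np.sum((rec.apply(moved) - pts) ** 2, axis=1)))
        assert err < 0.5


def test_icp_stationary_at_optimum(shell_mesh):
    mesh = shell_mesh
    pts = mesh.vertices[::7]
    history = []
    rec, rms, n_iter = icp_refine(
        pts, mesh.vertices, mesh.faces,
        init=RigidTransform.identity(), rms_history=history,
    )
    assert rms < 1e-9
    assert n_iter <= 2
    assert np.allclose(rec.rotation, np.eye(3), atol=1e-9)


def test_icp_rms_sequence_non_increasing(shell_mesh):
    mesh = shell_mesh
    rng = np.random.default_rng(3)
    pts = mesh.vertices[rng.choice(len(mesh.vertices), 200, replace=False)]
    T = RigidTransform.from_axis_angle([1, 1, 0], 20.0, (6.0, -4.0, 3.0))
    history = []
    icp_refine(
        T.apply(pts), mesh.vertices, mesh.faces,
        init=RigidTransform.identity(), rms_history=history,
    )
    assert len(history) >= 2
    assert all(a >= b - 1e-12 for a, b in zip(history, history[1:]))


def test_map_points_to_nodes_rules_and_oracle():
    rng = np.random.default_rng(31)
    nodes = rng.uniform(0, 30, size=(800, 3))
    # coincident point
    ids, d = map_points_to_nodes(nodes[5][None], nodes, radius_mm=1.0)
    assert ids[0] == 5 and d[0] == 0.0
    # a point farther than the radius from every node stays unassigned
    far = nodes.mean(axis=0) + np.array([100.0, 0.0, 0.0])
    ids, d = map_points_to_nodes(far[None], nodes, radius_mm=1.0)
    assert ids[0] == -1 and np.isinf(d[0])
    # brute-force nearest-node oracle on 1000 query points
    query = rng.uniform(0, 30, size=(1000, 3))
    ids, d = map_points_to_nodes(query, nodes, radius_mm=1.0)
    d2 = ((query[:, None, :] - nodes[None, :, :]) ** 2).sum(-1)
    brute_ids = d2.argmin(1)
    brute_d = np.sqrt(d2.min(1))
    expect = np.where(brute_d <= 1.0, brute_ids, -1)
    assert np.array_equal(ids, expect)
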