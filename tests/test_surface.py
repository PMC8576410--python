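"""Surface meshes, RBF thickness gradients, steep regions, distance maps."""

import numpy as np
import pytest

from vtsubstrate.surface import (
    GradientField,
    SurfaceMesh,
    average_to_vertices,
    distance_to_set,
    extract_surface_mesh,
    percentile_threshold,
    rbf_gradient,
    steep_regions,
)


def plane_mesh(nx=25, ny=25, step=1.0):
    """Triangulated grid, nominally planar with a tiny seeded ripple.

    The ripple (1e-3 mm) keeps the vertices non-coplanar: the thin-plate
    spline's linear polynomial tail is singular on exactly coplanar data.
    """
    xs = np.arange(nx) * step
    ys = np.arange(ny) * step
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    z = 1e-3 * np.sin(X) * np.cos(Y)
    verts = np.column_stack([X.ravel(), Y.ravel(), z.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            faces.append([a, a + ny, a + 1])
            faces.append([a + 1, a + ny, a + ny + 1])
    return SurfaceMesh(vertices=verts, faces=np.asarray(faces))


def test_shell_endo_mesh_geometry(shell_phantom):
    _, labels, _, _ = shell_phantom
    mesh = extract_surface_mesh(labels, "endo")
    radii = np.linalg.norm(mesh.vertices, axis=1)
    assert abs(radii.mean() - 20.0) < 0.6
    assert len(mesh.vertices) > 0
    assert mesh.faces.min() >= 0 and mesh.faces.max() < len(mesh.vertices)
    assert mesh.area() == pytest.approx(4 * np.pi * 20.0**2, rel=0.05)
    epi = extract_surface_mesh(labels, "epi")
    assert np.linalg.norm(epi.vertices, axis=1).mean() > 28.5
    with pytest.raises(ValueError):
        extract_surface_mesh(labels, "pericardium")


def test_rbf_constant_field_zero_gradient():
    mesh = plane_mesh()
    g = rbf_gradient(mesh, np.full(len(mesh.vertices), 7.0), smoothing=0.0)
    assert g.magnitude.max() < 1e-6


def test_rbf_linear_field_reproduced():
    mesh = plane_mesh()
    thickness = 2.0 + 0.3 * mesh.vertices[:, 0]
    g = rbf_gradient(mesh, thickness, smoothing=0.0)
    interior = (
        (mesh.vertices[:, 0] > 2)
        & (mesh.vertices[:, 0] < 22)
        & (mesh.vertices[:, 1] > 2)
        & (mesh.vertices[:, 1] < 22)
    )
    assert np.allclose(g.magnitude[interior], 0.3, rtol=0.01)
    # with zero smoothing the interpolant reproduces its training values
    assert np.allclose(g.interpolant(mesh.vertices), thickness, atol=1e-6)


def test_rbf_step_gradient_matches_graph_finite_differences():
    mesh = plane_mesh()
    x = mesh.vertices[:, 0]
    thickness = 10.0 - 6.0 / (1.0 + np.exp(-(x - 12.0)))  # 10 -> 4 mm step
    g = rbf_gradient(mesh, thickness, smoothing=0.0)
    # graph finite-difference oracle: max |dT/edge length| over incident edges
    e = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    dt = np.abs(thickness[e[:, 0]] - thickness[e[:, 1]])
    dl = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    fd = np.zeros(len(mesh.vertices))
    np.maximum.at(fd, e[:, 0], dt / dl)
    np.maximum.at(fd, e[:, 1], dt / dl)
    # both localize the maximal gradient at the step
    assert abs(x[np.argmax(g.magnitude)] - 12.0) <= 1.5
    assert abs(x[np.argmax(fd)] - 12.0) <= 1.5
    assert g.magnitude.max() == pytest.approx(fd.max(), rel=0.25)


def test_rbf_requires_enough_vertices():
    mesh = plane_mesh(nx=3, ny=3)
    vals = np.full(9, np.nan)
    vals[:5] = 1.0
    with pytest.raises(ValueError):
        rbf_gradient(mesh, vals)


def test_steep_regions_thresholding():
    mesh = plane_mesh()
    x = mesh.vertices[:, 0]
    thickness = 10.0 - 6.0 / (1.0 + np.exp(-(x - 12.0)))
    g = rbf_gradient(mesh, thickness, smoothing=0.0)
    above_max, n = steep_regions(g, g.magnitude.max() + 1.0)
    assert len(above_max) == 0 and n == 0
    ids, n = steep_regions(g, 0.5)
    assert n == 1  # a single band at the step
    assert np.all(np.abs(x[ids] - 12.0) < 6.0)
    # lowering the threshold grows the subset monotonically
    sizes = [len(steep_regions(g, thr)[0]) for thr in (1.0, 0.5, 0.25, 0.1)]
    assert all(a <= b for a, b in zip(sizes, sizes[1:]))
    assert percentile_threshold(g, 90.0) > 0


def test_distance_to_set_against_brute_force():
    rng = np.random.default_rng(11)
    query = rng.uniform(-50, 50, size=(500, 3))
    target = rng.uniform(-50, 50, size=(400, 3))
    fast = distance_to_set(query, target)
    brute = np.sqrt(((query[:, None, :] - target[None, :, :]) ** 2).sum(-1)).min(1)
    assert np.allclose(fast, brute, atol=1e-12)
    # membership means zero distance
    assert distance_to_set(target[:5], target)[0] == 0.0
    # adding a target point never increases any distance
    bigger = distance_to_set(query, np.vstack([target, rng.uniform(-50, 50, (1, 3))]))
    assert np.all(bigger <= fast + 1e-12)


def test_distance_to_set_is_lipschitz():
    rng = np.random.default_rng(12)
    target = rng.uniform(0, 10, size=(50, 3))
    p = rng.uniform(0, 10, size=(200, 3))
    q = rng.uniform(0, 10, size=(200, 3))
    dp = distance_to_set(p, target)
    dq = distance_to_set(q, target)
    assert np.all(np.abs(dp - dq) <= np.linalg.norm(p - q, axis=1) + 1e-12)


def test_distance_to_empty_target_warns():
    with pytest.warns(UserWarning, match="empty target"):
        d = distance_to_set(np.zeros((3, 3)), np.empty((0, 3)))
    assert np.all(np.isinf(d))


def test_average_to_vertices_denoises():
    rng = np.random.default_rng(13)
    nodes = rng.uniform(0, 20, size=(800, 3))
    vals = 5.0 + rng.normal(0, 0.3, size=800)  # constant field + jitter
    verts = rng.uniform(2, 18, size=(100, 3))
    smoothed = average_to_vertices(nodes, vals, verts, radius_mm=3.0)
    # jitter shrinks by roughly sqrt(neighborhood size)
    assert np.abs(smoothed - 5.0).mean() < np.abs(vals - 5.0).mean() / 2
    assert np.abs(smoothed - 5.0).max() < 0.45
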