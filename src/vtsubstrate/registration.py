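"""Rigid co-registration of electroanatomic point clouds with imaging meshes.

The mapping-system geometry lives in its own coordinate frame.  Alignment is
the field's standard two-stage recipe: a landmark (Procrustes/Kabsch) fit on
paired fiducials — coronary-ostia-like landmarks plus the LV apex — followed
by iterative-closest-point refinement against the imaging-derived surface.
Registered points are then assigned to mesh nodes within a fixed radius
(1 mm by default) for node-wise substrate assessment.

Transforms are rigid (6 degrees of freedom, no scaling): both geometries
come from the same ventricle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` in world millimetres."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("improper rotation (det = -1) is not a rigid motion")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass
class MappedPoint:
    """An electroanatomic point after registration and node assignment."""

    original_position: np.ndarray
    position: np.ndarray  # registered, world mm
    category: str  # 'normal' | 'diastolic'
    phase: Optional[str] = None  # 'early' | 'mid' | 'late' for diastolic points
    activation_time_ms: float = np.nan
    node_id: Optional[int] = None  # assigned mesh vertex, None if unassigned
    assignment_distance_mm: float = np.nan


def landmark_align(
    fixed: np.ndarray, moving: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform taking ``moving`` fiducials onto ``fixed``.

    Kabsch/Procrustes without scaling; reflections are excluded so the result
    is always a proper rotation.  Returns the transform and the fiducial RMS
    distance (mm) after alignment.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(
            f"fiducial count mismatch: {fixed.shape[0]} fixed vs {moving.shape[0]} moving"
        )
    if fixed.shape[0] < 3:
        raise ValueError("at least 3 paired fiducials are required")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    H = (moving - mc).T @ (fixed - fc)
    # Collinear fiducials leave a rotation about their axis undetermined.
    if np.linalg.matrix_rank(moving - mc, tol=1e-9) < 2:
        raise ValueError("fiducials are collinear; rotation is underdetermined")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    transform = RigidTransform(R, t)
    resid = transform.apply(moving) - fixed
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms


class _TriangleSurface:
    """Closest-point queries against a triangle mesh.

    Candidate triangles come from a KD-tree over triangle centroids; the exact
    closest point on each candidate is then computed in a vectorized
    point-triangle projection, so queries stay fast without spatial-index
    extras.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 12):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=int)
        if self.faces.size == 0:
            raise ValueError("mesh has no faces")
        self.tri = self.vertices[self.faces]  # (F, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self.k = min(k, len(self.faces))
        self._tree = cKDTree(self.centroids)

    def closest_points(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(points, k=self.k)
        cand = np.atleast_2d(cand)
        tri = self.tri[cand]  # (N, k, 3, 3)
        closest = _closest_point_on_triangles(points[:, None, :], tri)
        d2 = np.sum((closest - points[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return closest[rows, best], np.sqrt(d2[rows, best])


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query (Ericson's algorithm).

    ``p`` broadcasts against ``tri[..., 0, :]``; fully vectorized.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom = vc + vb + va
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom != 0, vb / denom, 0.0)
        w_face = np.where(denom != 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        ratio_bc = np.where(
            (d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0
        )

    out = a + v_face[..., None] * ab + w_face[..., None] * ac  # interior default
    # edge BC region
    mask = (d4 - d3 >= 0) & (d5 - d6 >= 0) & (va <= 0)
    out = np.where(mask[..., None], b + ratio_bc[..., None] * (c - b), out)
    # edge AC region
    mask = (d2 >= 0) & (d6 <= 0) & (vb <= 0)
    out = np.where(mask[..., None], a + w_ac[..., None] * ac, out)
    # edge AB region
    mask = (d1 >= 0) & (d3 <= 0) & (vc <= 0)
    out = np.where(mask[..., None], a + v_ab[..., None] * ab, out)
    # vertex regions
    mask = (d6 >= 0) & (d5 <= d6)
    out = np.where(mask[..., None], c, out)
    mask = (d3 >= 0) & (d4 <= d3)
    out = np.where(mask[..., None], b, out)
    mask = (d1 <= 0) & (d2 <= 0)
    out = np.where(mask[..., None], a, out)
    return out


def icp_refine(
    moving: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    init: RigidTransform,
    max_iter: int = 100,
    conv_tol_mm: float = 1e-4,
    trim_fraction: float = 0.1,
    rms_history: list | None = None,
) -> tuple[RigidTransform, float, int]:
    """Refine a rigid transform by iterative closest point against a surface.

    Correspondences are point-to-closest-surface-point; the worst
    ``trim_fraction`` of correspondences is dropped each iteration to
    robustify against partial overlap.  Iterates until the trimmed RMS
    changes by less than ``conv_tol_mm``.  The reported RMS sequence is
    non-increasing: an update that would raise it is rejected and iteration
    stops.

    Returns ``(transform, final_rms_mm, n_iterations)``.
    """
    moving = np.atleast_2d(np.asarray(moving, dtype=float))
    surface = _TriangleSurface(vertices, faces)
    n_keep = max(3, int(np.ceil(len(moving) * (1.0 - trim_fraction))))

    transform = init
    current = transform.apply(moving)
    closest, dists = surface.closest_points(current)
    keep = np.argsort(dists)[:n_keep]
    best_rms = float(np.sqrt(np.mean(dists[keep] ** 2)))
    if rms_history is not None:
        rms_history.append(best_rms)

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        step, _ = landmark_align(closest[keep], current[keep])
        candidate = step.compose(transform)
        cand_pts = candidate.apply(moving)
        cand_closest, cand_dists = surface.closest_points(cand_pts)
        cand_keep = np.argsort(cand_dists)[:n_keep]
        rms = float(np.sqrt(np.mean(cand_dists[cand_keep] ** 2)))
        if rms > best_rms:
            break  # reject non-improving update, keep monotone RMS
        improved = best_rms - rms
        transform, current = candidate, cand_pts
        closest, keep, best_rms = cand_closest, cand_keep, rms
        if rms_history is not None:
            rms_history.append(best_rms)
        if improved < conv_tol_mm:
            break
    return transform, best_rms, n_iter


def map_points_to_nodes(
    points: np.ndarray, vertices: np.ndarray, radius_mm: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each registered point to its nearest mesh node within a radius.

    Points farther than ``radius_mm`` from every node are left unassigned
    (id -1, distance inf).  Nearest-neighbor ties resolve to the lowest node
    id (cKDTree's deterministic order).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(np.asarray(vertices, dtype=float))
    dists, ids = tree.query(points)
    ids = np.asarray(ids, dtype=int)
    dists = np.asarray(dists, dtype=float)
    unassigned = dists > radius_mm
    ids[unassigned] = -1
    dists[unassigned] = np.inf
    return ids, dists
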