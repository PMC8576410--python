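"""Laplace potential across the myocardial wall.

The transmural coordinate is the harmonic function u solving ∇²u = 0 on the
myocardium with Dirichlet conditions u = 0 on the endocardial surface and
u = 1 on the epicardial surface.  Streamlines of ∇u then connect the two
surfaces without crossing, giving a wall-thickness measure that is
well-defined even in strongly curved or thinned wall (see
:mod:`vtsubstrate.streamlines`).

Discretization: 7-point finite differences on the voxel lattice, with the
Dirichlet surfaces imposed *between* voxel centers on each myocardium→blood
(u = 0) and myocardium→background (u = 1) edge via one-sided ghost
coefficients (Gibou–Fedkiw embedded boundary).  The sub-voxel crossing
position along each boundary edge is estimated from the 0.5 level-set of a
Gaussian-smoothed binary indicator of the far phase — for a smooth anatomy
this level-set tracks the true surface to O(h²), removing most of the
voxel-staircase error and letting the discrete solution match analytic
solutions to ~1e-2 at 1.2 mm spacing.  On a flat interface the estimate
reduces exactly to the face midpoint.  Untagged wall edges (e.g. the cut
base of a truncated ventricle, or the lattice boundary) receive mirror
(zero-flux) conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import cg, spsolve

from .grid import BACKGROUND, BLOOD, Volume, myocardium_mask

_OUTSIDE = -1  # sentinel for off-lattice neighbors (mirror condition)


@dataclass
class PotentialField:
    """Solution of the transmural Laplace problem on a label volume."""

    u: np.ndarray  # 3D, nan outside myocardium
    volume: Volume  # lattice carrying spacing/origin (label volume)
    endo_mask: np.ndarray
    epi_mask: np.ndarray
    myo_mask: np.ndarray
    residual: float  # max |A u - b| achieved

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volume.spacing


def tag_surfaces(labels: Volume) -> tuple[np.ndarray, np.ndarray]:
    """Tag endocardial and epicardial surface voxels of the myocardium.

    Endocardium = myocardial voxels face-adjacent (6-connectivity) to the
    blood pool; epicardium = myocardial voxels face-adjacent to background.
    A voxel adjacent to both (wall locally thinner than two voxels) is
    assigned by majority face count, endocardial on an exact tie, and a
    warning is emitted.
    """
    myo = myocardium_mask(labels)
    blood = labels.data == BLOOD
    bg = labels.data == BACKGROUND
    if not myo.any() or not blood.any():
        raise ValueError("volume must contain myocardium and blood pool")

    n_blood = _face_neighbor_count(blood)
    n_bg = _face_neighbor_count(bg)
    endo = myo & (n_blood > 0)
    epi = myo & (n_bg > 0)
    both = endo & epi
    if both.any():
        warnings.warn(
            f"{int(both.sum())} voxels adjacent to both blood and background "
            "(wall locally < 2 voxels thick); tagging by majority adjacency",
            stacklevel=2,
        )
        endo_wins = n_blood >= n_bg  # tie -> endocardium
        endo = endo & (~both | endo_wins)
        epi = epi & (~both | ~endo_wins)
    return endo, epi


def _face_neighbor_count(mask: np.ndarray) -> np.ndarray:
    """Number of 6-neighbors of each voxel lying in ``mask``."""
    m = mask.astype(np.int8)
    count = np.zeros(mask.shape, dtype=np.int8)
    for axis in range(3):
        for shift in (1, -1):
            count += _shifted(m, axis, shift, fill=0)
    return count


def _shifted(arr: np.ndarray, axis: int, shift: int, fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if shift > 0:
        src[axis] = slice(0, -shift)
        dst[axis] = slice(shift, None)
    else:
        src[axis] = slice(-shift, None)
        dst[axis] = slice(0, shift)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def solve_laplace(
    labels: Volume,
    tol: float = 1e-6,
    max_iter: int = 20000,
    boundary_sigma: float = 1.0,
) -> PotentialField:
    """Solve the transmural Laplace problem on a label volume.

    Uses a direct sparse solve for small systems and conjugate gradients
    (the operator is symmetric positive definite) for large ones, then
    verifies the max-norm residual against ``tol``.
    """
    myo = myocardium_mask(labels)
    endo, epi = tag_surfaces(labels)
    if not endo.any() or not epi.any():
        raise ValueError("both endocardial and epicardial surfaces must be nonempty")
    _, n_comp = ndimage.label(myo)
    if n_comp != 1:
        raise ValueError(f"myocardium must be a single connected component, got {n_comp}")

    lab = labels.data
    n = int(myo.sum())
    index = np.full(lab.shape, -1, dtype=np.int64)
    index[myo] = np.arange(n)

    # Dimensionless per-axis weights (h_min / h_axis)^2; unity when isotropic.
    h = np.asarray(labels.spacing)
    w_axis = (h.min() / h) ** 2

    # Smoothed phase indicators for sub-voxel boundary localization.  The
    # 0.5 level of a Gaussian-smoothed indicator is displaced from the true
    # surface by ~sigma^2 * (mean curvature); estimating the crossing at two
    # smoothing scales and extrapolating linearly in sigma^2 cancels that
    # curvature bias while keeping the staircase suppression.
    sigma = boundary_sigma
    chi = {
        phase: [
            ndimage.gaussian_filter((lab == code).astype(float), sigma=s)
            for s in (sigma, sigma * np.sqrt(2.0))
        ]
        for phase, code in (("blood", BLOOD), ("bg", BACKGROUND))
    }

    def _alpha_single(chi_c, chi_n):
        denom = chi_n - chi_c
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(denom > 1e-9, (0.5 - chi_c) / denom, 0.5)
        return np.clip(a, 0.1, 1.5)

    def crossing_fraction(phase, axis, shift):
        """Fractional distance center→neighbor of the interface crossing."""
        a_pair = [
            _alpha_single(c[myo], _shifted(c, axis, shift, fill=0.0)[myo])
            for c in chi[phase]
        ]
        alpha = 2.0 * a_pair[0] - a_pair[1]  # extrapolate sigma^2 -> 0
        # small fractions are fine: the 1/alpha coefficient just ties the
        # node tightly to the nearby boundary value (diagonally dominant)
        return np.clip(alpha, 0.05, 1.0)

    diag = np.zeros(n)
    b = np.zeros(n)
    rows_off, cols_off, vals_off = [], [], []
    for axis in range(3):
        w = w_axis[axis]
        for shift in (1, -1):
            nb_lab = _shifted(lab, axis, shift, fill=_OUTSIDE)[myo]
            nb_idx = _shifted(index, axis, shift, fill=-1)[myo]
            is_myo = nb_idx >= 0
            diag[is_myo] -= w
            rows_off.append(np.nonzero(is_myo)[0])
            cols_off.append(nb_idx[is_myo])
            vals_off.append(np.full(int(is_myo.sum()), w))
            is_blood = nb_lab == BLOOD
            is_bg = nb_lab == BACKGROUND
            # ghost: u = 0 (blood) / u = 1 (background) at the estimated
            # sub-voxel crossing, a fraction alpha of the edge from center
            alpha_b = crossing_fraction("blood", axis, shift)
            alpha_g = crossing_fraction("bg", axis, shift)
            diag[is_blood] -= w / alpha_b[is_blood]
            diag[is_bg] -= w / alpha_g[is_bg]
            b[is_bg] -= w / alpha_g[is_bg]
            # anything else (off-lattice / excluded) mirrors: no contribution

    rows = np.concatenate(rows_off + [np.arange(n)])
    cols = np.concatenate(cols_off + [np.arange(n)])
    vals = np.concatenate(vals_off + [diag])
    A = csr_matrix((vals, (rows, cols)), shape=(n, n))

    if n <= 20000:
        u = spsolve((-A).tocsc(), -b)
    else:
        u, info = cg(-A, -b, rtol=1e-12, atol=0.0, maxiter=max_iter)
        if info > 0:
            resid = float(np.abs(A @ u - b).max())
            if resid > tol:
                raise RuntimeError(
                    f"Laplace solve did not converge in {max_iter} iterations "
                    f"(max residual {resid:.2e} > tol {tol:.0e})"
                )
    residual = float(np.abs(A @ u - b).max())
    if residual > tol:
        raise RuntimeError(f"Laplace residual {residual:.2e} exceeds tol {tol:.0e}")

    ugrid = np.full(lab.shape, np.nan)
    ugrid[myo] = u
    return PotentialField(
        u=ugrid,
        volume=labels,
        endo_mask=endo,
        epi_mask=epi,
        myo_mask=myo,
        residual=residual,
    )
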