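"""Synthetic left-ventricular phantoms with voxel-exact ground truth.

The study conditions these phantoms emulate: a high-resolution 3D LGE
acquisition at 1.2 mm isotropic resolution of an LV wall containing a
healed antero-septal infarct — dense scar of controlled transmural extent
growing from the endocardium, ringed by a rim of intermediate-intensity
heterogeneous tissue (HT), with wall thinning toward the scar core — plus
electroanatomic mapping exports recorded in a displaced coordinate frame
and activation maps containing lines of conduction block.

Three wall geometries are available:

``slab``
    A flat wall of constant thickness between a blood layer and background;
    the analytic workhorse (true thickness is exact everywhere).
``spherical_shell``
    Wall between concentric spheres, optionally thinned inside scar patches
    so that thickness, thickness gradients, and distance metrics all have
    analytic ground truth per endocardial node.
``truncated_ellipsoid``
    LV-like half-ellipsoid cut at a base plane (the cut face coincides with
    the grid edge and therefore receives the zero-flux boundary condition
    downstream); the apex is the point farthest from the base plane.

Every output is a deterministic function of the spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .egm import ActivationMap
from .grid import BACKGROUND, BLOOD, HT, NORMAL, SCAR, Volume
from .registration import RigidTransform

#: Class-mean signal intensities (arbitrary units).  Chosen so the
#: 40% / 60%-of-max thresholds bracket the HT mean symmetrically:
#: with max SI 100 the thresholds sit at 40 and 60, recovering the true
#: classes exactly on a noiseless phantom.
DEFAULT_INTENSITY_MEANS = {
    BACKGROUND: 5.0,
    BLOOD: 70.0,
    NORMAL: 20.0,
    HT: 50.0,
    SCAR: 100.0,
}


@dataclass
class ScarPatch:
    """A scar patch on the wall.

    ``center`` is interpreted per geometry: an (x, y) mm position on the
    slab mid-plane, or a direction vector from the chamber center for the
    shell / ellipsoid.  ``extent`` is the patch radius: mm on the slab,
    degrees of angular radius otherwise.  Scar occupies the wall from the
    endocardial side up to ``transmural_fraction`` of the local wall depth
    and is ringed by HT of width ``ht_rim_width_mm``.
    """

    center: tuple
    extent: float
    transmural_fraction: float = 0.5
    ht_rim_width_mm: float = 2.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.transmural_fraction <= 1.0:
            raise ValueError(
                f"transmural_fraction must be in [0, 1], got {self.transmural_fraction}"
            )
        if self.ht_rim_width_mm < 0:
            raise ValueError("ht_rim_width_mm must be >= 0")
        if self.extent <= 0:
            raise ValueError("patch extent must be positive")


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom.

    Identical spec + seed reproduces identical outputs bit-for-bit.
    """

    shape_kind: str = "spherical_shell"  # slab | spherical_shell | truncated_ellipsoid
    voxel_spacing_mm: float = 1.2
    # slab geometry
    slab_thickness_mm: float = 10.0
    slab_extent_mm: float = 48.0
    # shell geometry (healthy wall = r_epi - r_endo)
    shell_r_endo_mm: float = 20.0
    shell_r_epi_mm: float = 28.4
    # ellipsoid geometry: endocardial semi-axes, constant wall, base plane
    ellipsoid_semi_axes_mm: tuple = (18.0, 18.0, 30.0)
    ellipsoid_wall_mm: float = 8.4
    ellipsoid_base_fraction: float = 0.3  # base plane at z = fraction * c
    # wall thinning inside scar patches: minimum thickness = factor * healthy
    thinning_factor: float = 0.5
    scar_patches: list = field(default_factory=list)
    intensity_means: dict = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS)
    )
    noise_sd: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_kind not in ("slab", "spherical_shell", "truncated_ellipsoid"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel_spacing_mm must be positive")
        if self.slab_thickness_mm <= 0 or self.slab_extent_mm <= 0:
            raise ValueError("slab extents must be positive")
        if not 0 < self.shell_r_endo_mm < self.shell_r_epi_mm:
            raise ValueError("need 0 < shell_r_endo_mm < shell_r_epi_mm")
        if not 0 < self.thinning_factor <= 1.0:
            raise ValueError("thinning_factor must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for p in self.scar_patches:
            self._check_patch(p)

    def _check_patch(self, patch: ScarPatch) -> None:
        if self.shape_kind == "slab":
            cx, cy = patch.center
            half = self.slab_extent_mm / 2.0
            if abs(cx) + patch.extent > half or abs(cy) + patch.extent > half:
                raise ValueError(
                    f"scar patch (center {patch.center}, radius {patch.extent} mm) "
                    f"exceeds the {self.slab_extent_mm} mm slab extent"
                )
        else:
            if patch.extent >= 90.0:
                raise ValueError(
                    f"angular patch radius {patch.extent} deg exceeds a hemisphere"
                )

    @property
    def healthy_thickness_mm(self) -> float:
        if self.shape_kind == "slab":
            return self.slab_thickness_mm
        if self.shape_kind == "spherical_shell":
            return self.shell_r_epi_mm - self.shell_r_endo_mm
        return self.ellipsoid_wall_mm


@dataclass
class GroundTruth:
    """Analytic ground truth for every quantity measured downstream."""

    spec: PhantomSpec
    voxel_labels: np.ndarray  # true class per voxel
    depth_fraction: np.ndarray  # normalized wall depth per voxel (nan off-wall)
    endo_indices: np.ndarray  # (N, 3) voxel indices of endocardial nodes
    endo_points: np.ndarray  # (N, 3) world mm
    true_thickness_mm: np.ndarray  # (N,)
    true_scar_fraction: np.ndarray  # (N,) transmural fraction in [0, 1]
    true_ht_fraction: np.ndarray  # (N,)
    fiducials: dict  # name -> (3,) world mm, image frame
    eam_transform: Optional[RigidTransform] = None  # frame applied to exports
    block_polylines: list = field(default_factory=list)
    block_total_length_mm: float = 0.0


# ---------------------------------------------------------------------------
# geometry helpers


def _patch_direction(center) -> np.ndarray:
    d = np.asarray(center, dtype=float)
    return d / np.linalg.norm(d)


def _thickness_profile(spec: PhantomSpec, dirs: np.ndarray) -> np.ndarray:
    """Local wall thickness for unit directions (shell / ellipsoid).

    Healthy thickness outside patches; inside a patch the wall thins with a
    cosine ramp from healthy at the patch border down to
    ``thinning_factor * healthy`` over the outer half of the patch, and is
    uniformly thin over the inner half.  The ramp concentrates the steep
    thickness gradient at the scar border zone, as seen around healed
    infarcts.
    """
    dirs = np.atleast_2d(dirs)
    t_healthy = spec.healthy_thickness_mm
    thickness = np.full(len(dirs), t_healthy)
    t_min = spec.thinning_factor * t_healthy
    for patch in spec.scar_patches:
        pc = _patch_direction(patch.center)
        ang = np.degrees(np.arccos(np.clip(dirs @ pc, -1.0, 1.0)))
        theta = patch.extent
        ramp = np.clip((ang - 0.5 * theta) / (0.5 * theta), 0.0, 1.0)
        local = t_min + (t_healthy - t_min) * 0.5 * (1 - np.cos(np.pi * ramp))
        thickness = np.minimum(thickness, np.where(ang <= theta, local, t_healthy))
    return thickness


def _endo_radius(spec: PhantomSpec, dirs: np.ndarray) -> np.ndarray:
    dirs = np.atleast_2d(dirs)
    if spec.shape_kind == "spherical_shell":
        return np.full(len(dirs), spec.shell_r_endo_mm)
    a, b, c = spec.ellipsoid_semi_axes_mm
    q = (dirs[:, 0] / a) ** 2 + (dirs[:, 1] / b) ** 2 + (dirs[:, 2] / c) ** 2
    return 1.0 / np.sqrt(np.maximum(q, 1e-12))  # guard the degenerate origin


def _grid_axes(spec: PhantomSpec):
    """Voxel-center axes and origin per geometry."""
    h = spec.voxel_spacing_mm
    if spec.shape_kind == "slab":
        half = spec.slab_extent_mm / 2.0
        nxy = int(round(spec.slab_extent_mm / h))
        xy = (np.arange(nxy) + 0.5) * h - half
        n_blood, n_bg = 4, 3
        nz = n_blood + int(np.ceil(spec.slab_thickness_mm / h)) + n_bg
        z = (np.arange(nz) + 0.5) * h - n_blood * h
        return xy, xy, z
    if spec.shape_kind == "spherical_shell":
        half = spec.shell_r_epi_mm + 3 * h
        n = 2 * int(np.ceil(half / h)) + 1
        ax = (np.arange(n) - (n - 1) / 2.0) * h
        return ax, ax, ax
    # truncated ellipsoid: grid top edge IS the base plane
    a, b, c = spec.ellipsoid_semi_axes_mm
    t = spec.ellipsoid_wall_mm
    hx = a + t + 3 * h
    hy = b + t + 3 * h
    nx = 2 * int(np.ceil(hx / h)) + 1
    ny = 2 * int(np.ceil(hy / h)) + 1
    x = (np.arange(nx) - (nx - 1) / 2.0) * h
    y = (np.arange(ny) - (ny - 1) / 2.0) * h
    z_base = spec.ellipsoid_base_fraction * c
    z_lo = -(c + t + 3 * h)
    nz = int(np.ceil((z_base - z_lo) / h))
    z = z_base - (np.arange(nz)[::-1] + 0.5) * h  # top voxel center h/2 below base
    return x, y, z


def _face_adjacent(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxels of ``mask_a`` sharing a face with ``mask_b`` (6-connectivity)."""
    struct = ndimage.generate_binary_structure(3, 1)
    return mask_a & ndimage.binary_dilation(mask_b, structure=struct)


# ---------------------------------------------------------------------------
# main constructors


def make_label_volume(spec: PhantomSpec) -> tuple[Volume, Volume, GroundTruth]:
    """Build the phantom label volume, intensity volume, and ground truth."""
    x, y, z = _grid_axes(spec)
    origin = (float(x[0]), float(y[0]), float(z[0]))
    h = spec.voxel_spacing_mm
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    labels = np.full(X.shape, BACKGROUND, dtype=np.int16)
    depth = np.full(X.shape, np.nan)

    if spec.shape_kind == "slab":
        T = spec.slab_thickness_mm
        labels[Z < 0] = BLOOD
        wall = (Z >= 0) & (Z < T)
        labels[wall] = NORMAL
        depth[wall] = Z[wall] / T
        dcmp = np.where(np.isnan(depth), np.inf, depth)
        scar = np.zeros_like(wall)
        for patch in spec.scar_patches:
            cx, cy = patch.center
            lateral = (X - cx) ** 2 + (Y - cy) ** 2 <= patch.extent**2
            scar |= wall & lateral & (dcmp <= patch.transmural_fraction)
    else:
        pos = np.stack([X, Y, Z], axis=-1)
        r = np.linalg.norm(pos, axis=-1)
        r_safe = np.where(r > 1e-9, r, 1.0)
        dirs = (pos / r_safe[..., None]).reshape(-1, 3)
        r_endo = _endo_radius(spec, dirs).reshape(r.shape)
        thick = _thickness_profile(spec, dirs).reshape(r.shape)
        r_epi = r_endo + thick
        labels[r < r_endo] = BLOOD
        wall = (r >= r_endo) & (r < r_epi)
        labels[wall] = NORMAL
        depth[wall] = ((r - r_endo) / thick)[wall]
        dcmp = np.where(np.isnan(depth), np.inf, depth)
        scar = np.zeros_like(wall)
        for patch in spec.scar_patches:
            pc = _patch_direction(patch.center)
            ang = np.degrees(
                np.arccos(np.clip(dirs @ pc, -1.0, 1.0))
            ).reshape(r.shape)
            scar |= wall & (ang <= patch.extent) & (dcmp <= patch.transmural_fraction)

    labels[scar] = SCAR
    # HT rim: myocardium within the rim width of scar, outside scar itself.
    rim_widths = {p.ht_rim_width_mm for p in spec.scar_patches}
    if scar.any() and any(w > 0 for w in rim_widths):
        rim = max(rim_widths)
        dist_to_scar = ndimage.distance_transform_edt(~scar, sampling=(h, h, h))
        ht = (labels == NORMAL) & (dist_to_scar <= rim)
        labels[ht] = HT

    myo = np.isin(labels, (NORMAL, HT, SCAR))
    _, n_comp = ndimage.label(myo)
    if n_comp == 0:
        raise ValueError("phantom produced no myocardium")

    vol = Volume(labels, (h, h, h), origin)

    # intensities
    rng = np.random.default_rng(spec.rng_seed)
    intensity = np.zeros(labels.shape)
    for cls, mean in spec.intensity_means.items():
        intensity[labels == cls] = mean
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=labels.shape)
    ivol = Volume(intensity, (h, h, h), origin)

    truth = _build_ground_truth(spec, vol, depth)
    return vol, ivol, truth


def _build_ground_truth(spec: PhantomSpec, vol: Volume, depth: np.ndarray) -> GroundTruth:
    labels = vol.data
    myo = np.isin(labels, (NORMAL, HT, SCAR))
    endo = _face_adjacent(myo, labels == BLOOD)
    endo_idx = np.argwhere(endo)
    endo_pts = vol.world_coords(endo_idx)

    n = len(endo_idx)
    thickness = np.full(n, spec.healthy_thickness_mm)
    scar_frac = np.zeros(n)
    ht_frac = np.zeros(n)

    if spec.shape_kind == "slab":
        for patch in spec.scar_patches:
            cx, cy = patch.center
            inside = (endo_pts[:, 0] - cx) ** 2 + (
                endo_pts[:, 1] - cy
            ) ** 2 <= patch.extent**2
            scar_frac[inside] = patch.transmural_fraction
            ht_frac[inside] = np.minimum(
                patch.ht_rim_width_mm / spec.slab_thickness_mm,
                1.0 - patch.transmural_fraction,
            )
        fid = {
            "apex": np.array([0.0, 0.0, 0.0]),
            "ostium_1": np.array([spec.slab_extent_mm / 2 - 2, 0.0, 0.0]),
            "ostium_2": np.array([0.0, spec.slab_extent_mm / 2 - 2, 0.0]),
            "ostium_3": np.array([-(spec.slab_extent_mm / 2 - 2), 0.0, 0.0]),
        }
    else:
        r = np.linalg.norm(endo_pts, axis=1)
        dirs = endo_pts / r[:, None]
        thickness = _thickness_profile(spec, dirs)
        for patch in spec.scar_patches:
            pc = _patch_direction(patch.center)
            ang = np.degrees(np.arccos(np.clip(dirs @ pc, -1.0, 1.0)))
            inside = ang <= patch.extent
            scar_frac[inside] = patch.transmural_fraction
            ht_frac[inside] = np.minimum(
                patch.ht_rim_width_mm / thickness[inside],
                1.0 - patch.transmural_fraction,
            )
        if spec.shape_kind == "spherical_shell":
            re = spec.shell_r_endo_mm
            base_dirs = [
                np.array([np.sin(np.pi / 6) * np.cos(az), np.sin(np.pi / 6) * np.sin(az), np.cos(np.pi / 6)])
                for az in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
            ]
            fid = {"apex": np.array([0.0, 0.0, -re])}
            for i, d in enumerate(base_dirs, start=1):
                fid[f"ostium_{i}"] = re * d
        else:
            a, b, c = spec.ellipsoid_semi_axes_mm
            zb = spec.ellipsoid_base_fraction * c
            # apex: farthest endocardial point from the base plane
            fid = {"apex": np.array([0.0, 0.0, -c])}
            ring_z = zb - 2.0
            for i, az in enumerate((0.0, 2 * np.pi / 3, 4 * np.pi / 3), start=1):
                rr = np.sqrt(max(1e-6, 1 - (ring_z / c) ** 2))
                fid[f"ostium_{i}"] = np.array(
                    [a * rr * np.cos(az), b * rr * np.sin(az), ring_z]
                )

    return GroundTruth(
        spec=spec,
        voxel_labels=labels.copy(),
        depth_fraction=depth,
        endo_indices=endo_idx,
        endo_points=endo_pts,
        true_thickness_mm=thickness,
        true_scar_fraction=scar_frac,
        true_ht_fraction=ht_frac,
        fiducials=fid,
    )


def make_eam_export(
    truth: GroundTruth,
    transform: RigidTransform | None = None,
    n_diastolic: int = 100,
    n_normal: int = 100,
    noise_sd_mm: float = 0.5,
    seed: int = 0,
    border_band_deg: float = 10.0,
    normal_margin_deg: float = 25.0,
    cycle_length_ms: float = 400.0,
    qrs_end_ms: float = 100.0,
) -> pd.DataFrame:
    """Export an electroanatomic point table in a displaced frame.

    Diastolic points are seeded around the scar border zone (within
    ``border_band_deg`` of the patch edge, inside and outside), matching
    where diastolic electrograms of the reentrant circuit localize; normal
    points are seeded in remote healthy wall at least ``normal_margin_deg``
    beyond any patch.  All positions lie on the true endocardial surface,
    are expressed in the displaced EAM frame (``transform`` applied, then
    Gaussian noise), and are accompanied by fiducial rows (apex + 3
    ostial landmarks).  Diastolic activation times fall in the diastolic
    window ``[qrs_end, cycle_length)``; normal times fall within the QRS.

    Columns: ``x, y, z, time_ms, category, label``.
    """
    spec = truth.spec
    if spec.shape_kind == "slab":
        raise ValueError("EAM export is defined for shell / ellipsoid phantoms")
    if not spec.scar_patches:
        raise ValueError("EAM export needs at least one scar patch (border seeding)")
    if n_diastolic + n_normal < 1:
        raise ValueError("need at least one mapping point beyond the fiducials")
    if transform is None:
        transform = RigidTransform.identity()
    rng = np.random.default_rng(seed)

    patch = spec.scar_patches[0]
    pc = _patch_direction(patch.center)

    def sample_dirs(n, accept):
        out = []
        while sum(len(o) for o in out) < n:
            cand = rng.normal(size=(4 * n, 3))
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            ang = np.degrees(np.arccos(np.clip(cand @ pc, -1.0, 1.0)))
            out.append(cand[accept(ang)])
        return np.vstack(out)[:n]

    dia_dirs = sample_dirs(
        n_diastolic,
        lambda a: np.abs(a - patch.extent) <= border_band_deg,
    )
    nrm_dirs = sample_dirs(
        n_normal, lambda a: a >= patch.extent + normal_margin_deg
    )

    dia_pos = dia_dirs * _endo_radius(spec, dia_dirs)[:, None]
    nrm_pos = nrm_dirs * _endo_radius(spec, nrm_dirs)[:, None]

    dia_t = rng.uniform(qrs_end_ms, cycle_length_ms, size=n_diastolic)
    nrm_t = rng.uniform(5.0, qrs_end_ms - 5.0, size=n_normal)

    fid_names = list(truth.fiducials)
    fid_pos = np.array([truth.fiducials[k] for k in fid_names])

    all_pos = np.vstack([fid_pos, dia_pos, nrm_pos])
    moved = transform.apply(all_pos)
    if noise_sd_mm > 0:
        moved = moved + rng.normal(0.0, noise_sd_mm, size=moved.shape)

    df = pd.DataFrame(moved, columns=["x", "y", "z"])
    df["time_ms"] = np.concatenate(
        [np.full(len(fid_names), np.nan), dia_t, nrm_t]
    )
    df["category"] = (
        ["fiducial"] * len(fid_names)
        + ["diastolic"] * n_diastolic
        + ["normal"] * n_normal
    )
    df["label"] = fid_names + [""] * (n_diastolic + n_normal)
    truth.eam_transform = transform
    return df


def make_activation_map(
    extent_mm: tuple[float, float] = (30.0, 30.0),
    grid_step_mm: float = 2.0,
    block: bool = True,
    block_offset_ms: float = 40.0,
    speed_mm_per_ms: float = 1.0,
    jitter_sd_mm: float = 0.15,
    rhythm: str = "VT",
    seed: int = 0,
) -> tuple[ActivationMap, dict]:
    """Kinematic activation map on a flat mapped patch, with optional block.

    With ``block=True`` two planar wavefronts travel toward each other and
    collide along the line x = 0 spanning the patch, with a time offset of
    ``block_offset_ms`` across it — a constructed line of block whose
    length equals the patch height.  With ``block=False`` a single planar
    wavefront crosses the patch and no adjacent-point gap exceeds the
    block threshold.

    Returns the map and a ground-truth dict with the constructed polyline
    and its arc length.
    """
    w, hgt = extent_mm
    rng = np.random.default_rng(seed)
    xs = np.arange(-w / 2, w / 2 + 1e-9, grid_step_mm)
    ys = np.arange(0.0, hgt + 1e-9, grid_step_mm)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    if jitter_sd_mm > 0:
        pts[:, :2] += rng.normal(0.0, jitter_sd_mm, size=(len(pts), 2))

    if block:
        left = pts[:, 0] < 0
        t = np.where(
            left,
            (pts[:, 0] + w / 2) / speed_mm_per_ms,
            (w / 2 - pts[:, 0]) / speed_mm_per_ms + block_offset_ms,
        )
        poly = np.array([[0.0, 0.0, 0.0], [0.0, hgt, 0.0]])
        truth = {
            "block_polylines": [poly],
            "block_total_length_mm": float(hgt),
            "n_block_regions": 1,
        }
    else:
        t = (pts[:, 0] + w / 2) / speed_mm_per_ms
        truth = {
            "block_polylines": [],
            "block_total_length_mm": 0.0,
            "n_block_regions": 0,
        }
    amap = ActivationMap(points=pts, times_ms=t, rhythm=rhythm)
    return amap, truth
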