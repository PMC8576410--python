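"""Voxel-grid containers shared by every stage of the pipeline.

Volumes are axis-aligned: world coordinates are ``origin + index * spacing``
(voxel centers), all in millimetres.  This mirrors a NIfTI volume with a
diagonal affine; :mod:`vtsubstrate.io` maps between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Tissue label vocabulary.  Scar and heterogeneous tissue (HT, the
# intermediate-intensity border zone) are geometric subsets of the
# myocardium, so myocardial masks are the union {NORMAL, HT, SCAR}.
BACKGROUND = 0
BLOOD = 1
NORMAL = 2
HT = 3
SCAR = 4

MYOCARDIUM_LABELS = (NORMAL, HT, SCAR)

LABEL_NAMES = {
    BACKGROUND: "background",
    BLOOD: "blood",
    NORMAL: "normal",
    HT: "ht",
    SCAR: "scar",
}


@dataclass
class Volume:
    """A 3D scalar or label grid with world-space placement.

    Parameters
    ----------
    data:
        3D array; integer dtype for label volumes, float for intensity.
    spacing:
        Voxel edge lengths in mm, one per axis, all positive.
    origin:
        World position (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.2, 1.2, 1.2)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensity volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World mm positions of (possibly fractional) voxel indices."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_coords(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world-mm points."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def like(self, data: np.ndarray) -> "Volume":
        """New volume on the same lattice with different data."""
        return Volume(data, self.spacing, self.origin)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


def myocardium_mask(labels: Volume) -> np.ndarray:
    """Boolean mask of all myocardial voxels (normal + HT + scar)."""
    return np.isin(labels.data, MYOCARDIUM_LABELS)
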