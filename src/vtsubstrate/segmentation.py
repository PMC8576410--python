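"""Max-referenced signal-intensity tissue classification.

Within a given myocardial segmentation, voxels at or above 60% of the
maximum signal intensity are classified as dense scar and voxels between
40% and 60% as intermediate-intensity heterogeneous tissue (HT / border
zone); the remainder is normal myocardium.  The reference maximum is taken
over the segmentation mask only, so the classification is invariant to any
positive rescaling of the intensities.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grid import HT, NORMAL, SCAR, Volume

SCAR_FRACTION = 0.60
HT_FRACTION = 0.40


def classify_tissue(
    intensity: Volume,
    myocardium_mask: np.ndarray,
    scar_frac: float = SCAR_FRACTION,
    ht_frac: float = HT_FRACTION,
    base_labels: Volume | None = None,
    min_component_voxels: int = 0,
) -> Volume:
    """Classify myocardial voxels into scar / HT / normal by relative SI.

    Thresholds are fractions of the maximum intensity M within the mask:
    SI >= scar_frac*M is scar, ht_frac*M <= SI < scar_frac*M is HT, below
    is normal.  Boundaries are inclusive at the lower edge of each class.
    Labels outside the mask are taken from ``base_labels`` when given
    (blood pool, background) and left untouched.

    ``min_component_voxels`` optionally removes scar/HT connected
    components smaller than the given size (off by default; no such
    clean-up is applied in the reference analysis).
    """
    mask = np.asarray(myocardium_mask, dtype=bool)
    if mask.shape != intensity.shape:
        raise ValueError("mask shape does not match intensity volume")
    if not mask.any():
        raise ValueError("myocardium mask is empty")
    if not 0.0 < ht_frac < scar_frac <= 1.0:
        raise ValueError(
            f"need 0 < ht_frac < scar_frac <= 1, got ht={ht_frac}, scar={scar_frac}"
        )
    si = intensity.data
    m = float(si[mask].max())
    if m <= 0:
        raise ValueError(f"maximum SI within mask is {m}; cannot threshold")

    if base_labels is not None:
        out = base_labels.data.copy()
    else:
        out = np.zeros(intensity.shape, dtype=np.int16)
    out[mask] = NORMAL
    ht_sel = mask & (si >= ht_frac * m) & (si < scar_frac * m)
    scar_sel = mask & (si >= scar_frac * m)
    out[ht_sel] = HT
    out[scar_sel] = SCAR

    if min_component_voxels > 0:
        for cls in (SCAR, HT):
            lab, n = ndimage.label(out == cls)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            small = np.isin(lab, np.nonzero(sizes < min_component_voxels)[0] + 1)
            out[small & (out == cls)] = NORMAL

    return intensity.like(out)
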