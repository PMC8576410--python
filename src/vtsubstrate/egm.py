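"""Activation-map analysis: diastolic-phase classification and conduction block.

Conduction block is operationalized from the mapping convention that a line
of block separates adjacent activation points whose local activation times
differ by more than 15 ms.  Points closer than ``neighbor_radius`` are
treated as adjacent; edges whose endpoint times differ by more than
``dt_block`` are block-crossing, and the block line is the polyline through
the midpoints of those edges.  Total block extent is the summed arc length
of the merged polylines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

DT_BLOCK_MS = 15.0  # adjacent-point activation-time difference defining block


@dataclass
class ActivationMap:
    """Mapped activation points plus derived conduction-block geometry."""

    points: np.ndarray  # (N, 3) world mm
    times_ms: np.ndarray  # (N,) local activation times
    cycle_length_ms: Optional[float] = None
    qrs_end_ms: Optional[float] = None  # start of the diastolic window
    rhythm: str = ""  # e.g. 'RVP500', 'RVP300', 'VT'
    block_polylines: list = field(default_factory=list)
    block_length_mm: float = 0.0
    n_block_regions: int = 0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if len(self.points) != len(self.times_ms):
            raise ValueError("points and times must have equal length")
        if not np.all(np.isfinite(self.times_ms)):
            raise ValueError("activation times must be finite")


def classify_diastolic_phase(
    t_ms: float, window_start_ms: float, window_end_ms: float
) -> str:
    """Classify a diastolic activation time as early, mid, or late.

    The diastolic window runs from the end of the QRS complex
    (``window_start_ms``) to ``window_end_ms`` and is split into equal
    tertiles with half-open boundaries ``[start, start + w/3)`` etc., so the
    classification is deterministic at the boundaries.
    """
    if not window_start_ms < window_end_ms:
        raise ValueError("window_start must precede window_end")
    if not (window_start_ms <= t_ms < window_end_ms):
        raise ValueError(
            f"time {t_ms} ms outside diastolic window "
            f"[{window_start_ms}, {window_end_ms}) — pre-filter diastolic points"
        )
    w = (window_end_ms - window_start_ms) / 3.0
    if t_ms < window_start_ms + w:
        return "early"
    if t_ms < window_start_ms + 2 * w:
        return "mid"
    return "late"


def detect_block_lines(
    amap: ActivationMap,
    dt_block_ms: float = DT_BLOCK_MS,
    neighbor_radius_mm: float = 5.0,
) -> ActivationMap:
    """Detect lines of conduction block on an activation point map.

    Builds the adjacency graph of points within ``neighbor_radius_mm``,
    flags edges whose activation-time difference exceeds ``dt_block_ms``,
    and reconstructs block lines as polylines through the midpoints of the
    flagged edges.  Midpoints are grouped into connected chains; within each
    chain they are binned along the chain's principal axis and the polyline
    runs through the bin centroids (a raw traversal of scattered midpoints
    would zigzag and inflate the arc length).

    Returns the map with ``block_polylines``, ``block_length_mm`` and
    ``n_block_regions`` populated.
    """
    pts = amap.points
    if len(pts) < 10:
        raise ValueError("need at least 10 activation points")
    tree = cKDTree(pts)
    pairs = tree.query_pairs(neighbor_radius_mm, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no adjacent points within neighbor_radius (degenerate map)")
    span = pts.max(axis=0) - pts.min(axis=0)
    if np.max(span) < 1e-9:
        raise ValueError("all points coincident")

    dt = np.abs(amap.times_ms[pairs[:, 0]] - amap.times_ms[pairs[:, 1]])
    crossing = pairs[dt > dt_block_ms]
    if len(crossing) == 0:
        amap.block_polylines = []
        amap.block_length_mm = 0.0
        amap.n_block_regions = 0
        return amap

    midpoints = 0.5 * (pts[crossing[:, 0]] + pts[crossing[:, 1]])

    # Group midpoints into chains (connected components within the radius).
    mtree = cKDTree(midpoints)
    mpairs = mtree.query_pairs(neighbor_radius_mm, output_type="ndarray")
    n = len(midpoints)
    if len(mpairs) > 0:
        adj = coo_matrix(
            (np.ones(len(mpairs)), (mpairs[:, 0], mpairs[:, 1])), shape=(n, n)
        )
        n_comp, comp = connected_components(adj, directed=False)
    else:
        n_comp, comp = n, np.arange(n)

    polylines = []
    total = 0.0
    for c in range(n_comp):
        chain = midpoints[comp == c]
        poly = _principal_axis_polyline(chain, bin_width=neighbor_radius_mm / 2.0)
        length = float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))
        polylines.append(poly)
        total += length
    amap.block_polylines = polylines
    amap.block_length_mm = total
    amap.n_block_regions = n_comp
    return amap


def _principal_axis_polyline(points: np.ndarray, bin_width: float) -> np.ndarray:
    """Ordered polyline through bin centroids along the principal axis."""
    if len(points) == 1:
        return np.vstack([points, points])
    center = points.mean(axis=0)
    centered = points - center
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ Vt[0]
    order = np.argsort(proj)
    proj = proj[order]
    pts = points[order]
    edges = np.arange(proj[0], proj[-1] + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([proj[0], proj[-1] + 1e-9])
    idx = np.clip(np.digitize(proj, edges) - 1, 0, len(edges) - 2)
    centroids = [pts[idx == b].mean(axis=0) for b in range(len(edges) - 1) if np.any(idx == b)]
    poly = np.asarray(centroids)
    if len(poly) == 1:
        poly = np.vstack([poly, poly])
    return poly


def block_extent_by_rhythm(maps: list[ActivationMap], **detect_kwargs) -> pd.DataFrame:
    """Total conduction-block length per activation map, keyed by rhythm.

    Runs :func:`detect_block_lines` on any map whose block geometry has not
    been computed yet.  One row per map, suitable for paired comparison of
    block extent across rhythms (e.g. RV pacing vs VT).
    """
    if len(maps) == 0:
        raise ValueError("need at least one activation map")
    rows = []
    for i, amap in enumerate(maps):
        if not amap.block_polylines and amap.block_length_mm == 0.0:
            detect_block_lines(amap, **detect_kwargs)
        rows.append(
            {
                "map_id": i,
                "rhythm": amap.rhythm,
                "block_length_mm": amap.block_length_mm,
                "n_block_regions": amap.n_block_regions,
                "n_points": len(amap.points),
            }
        )
    return pd.DataFrame(rows)
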