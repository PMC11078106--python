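"""Hull-based dendritic-field metrics, soma diameter, IPL depth profiles.

The dendritic-field diameter is reported as the equivalent circular
diameter of the 2D convex hull bounding the dendritic annotations,
2·sqrt(A/π) — robust to asymmetric fields.  IPL depth is expressed as a
percentage, 0 % at the INL/IPL boundary and 100 % at the IPL/GCL
boundary.  For ganglion-cell dendrites the mean depth is the standard
summary; for bipolar axon terminals the mode is preferred because the
long descending axon skews the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy import stats as _sstats

from .model import DegenerateGeometryError, IPLBoundaries, NeuronReconstruction


@dataclass
class HullMetrics:
    """Convex hull of a planar point set with derived field metrics."""

    vertices: np.ndarray  # (m, 2), counter-clockwise
    area: float  # µm²
    equivalent_diameter: float  # µm, 2·sqrt(area/π)
    centroid: tuple[float, float]  # polygon area centroid


@dataclass
class DepthProfile:
    depths: np.ndarray  # per-node IPL depth, %
    mean_depth: float
    mode_depth: float
    bin_width: float


def convex_hull_metrics(points: np.ndarray) -> HullMetrics:
    """Convex hull area, equivalent circular diameter, and area centroid.

    Raises :class:`DegenerateGeometryError` for <3 points or collinear input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 3:
        raise DegenerateGeometryError(f"need ≥3 points, got {len(pts)}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    verts = pts[hull.vertices]  # CCW in 2D
    # area centroid via the shoelace decomposition
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    area = abs(area)
    return HullMetrics(
        vertices=verts,
        area=float(area),
        equivalent_diameter=2.0 * math.sqrt(area / math.pi),
        centroid=(float(cx), float(cy)),
    )


def dendritic_field_hull(reconstruction: NeuronReconstruction) -> HullMetrics:
    """Hull of the dendrite-tagged annotations (soma and axon excluded)."""
    return convex_hull_metrics(reconstruction.dendrite_xy())


def soma_diameter(reconstruction: NeuronReconstruction) -> float:
    """Soma diameter = 2 × the maximum radius among soma-tagged disks."""
    somas = reconstruction.nodes_by_tag("soma")
    if not somas:
        raise ValueError(f"cell {reconstruction.cell_id} has no soma-tagged node")
    return 2.0 * max(n.radius for n in somas)


def depth_percent(z: np.ndarray, boundaries: IPLBoundaries) -> np.ndarray:
    """Map z (µm) to IPL depth %: 0 at INL/IPL, 100 at IPL/GCL."""
    span = boundaries.ipl_gcl_z - boundaries.inl_ipl_z
    return 100.0 * (np.asarray(z, dtype=float) - boundaries.inl_ipl_z) / span


def depth_profile(
    z_values: np.ndarray,
    boundaries: IPLBoundaries,
    bin_width: float = 1.0,
) -> DepthProfile:
    """Per-node IPL depths with mean and binned-mode summaries.

    The mode is the center of the most populated bin of width ``bin_width``
    (% units, bins aligned at 0); ties break toward the shallower bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    depths = depth_percent(z_values, boundaries)
    if depths.size == 0:
        raise ValueError("no depth values")
    idx = np.floor(depths / bin_width).astype(int)
    counts: dict[int, int] = {}
    for i in idx:
        counts[int(i)] = counts.get(int(i), 0) + 1
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return DepthProfile(
        depths=depths,
        mean_depth=float(depths.mean()),
        mode_depth=float((best + 0.5) * bin_width),
        bin_width=bin_width,
    )


def two_sample_t(a, b) -> tuple[float, float]:
    """Pooled-variance two-sided two-sample t test.

    With zero pooled variance and equal means, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n ≥ 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = _sstats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
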