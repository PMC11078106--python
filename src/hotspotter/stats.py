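"""Synapse-composition statistics: amacrine/bipolar proportions, the
geometric run-length null, consecutive-run detection along dendrites,
per-partner synapse profiles, classification rates, Fisher's exact test,
and overlap analysis against a reference dendritic field.

The null for N consecutive amacrine synapses uninterrupted by a bipolar
synapse is the geometric probability p^N, with p the per-synapse amacrine
probability (the ratio of amacrine synapses to total synaptic input; a
1.6:1 amacrine:bipolar cell ratio gives p = 1.6/2.6 ≈ 0.615, hence
p⁵ ≈ 8.8 % and p¹⁴ ≈ 0.1 %).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sstats
from shapely.geometry import Point, Polygon

from .model import (
    DegenerateGeometryError,
    NeuronReconstruction,
    SynapseRecord,
    attach_synapses,
)
from .morphometry import HullMetrics

#: geometric tolerance for boundary-inclusive membership, µm
_GEOM_TOL = 1e-9


def amacrine_probability(
    synapses: Optional[Sequence[SynapseRecord]] = None,
    ratio: Optional[tuple[float, float]] = None,
) -> float:
    """Per-synapse amacrine probability p.

    Either from a synapse table (conventional / total) or from an
    amacrine:bipolar ratio a:b, p = a/(a+b).
    """
    if (synapses is None) == (ratio is None):
        raise ValueError("pass exactly one of synapses or ratio")
    if ratio is not None:
        a, b = ratio
        if a < 0 or b < 0 or a + b <= 0:
            raise ValueError("ratio terms must be ≥ 0 with positive sum")
        return a / (a + b)
    if not synapses:
        raise ValueError("empty synapse table")
    n_am = sum(1 for s in synapses if s.kind == "conventional")
    return n_am / len(synapses)


def run_probability(p: float, N: int) -> float:
    """Geometric null probability p^N of N consecutive amacrine synapses."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if N < 0 or int(N) != N:
        raise ValueError("N must be a non-negative integer")
    return float(p) ** int(N)


@dataclass
class AmacrineRun:
    path_id: str
    length: int
    synapse_ids: list[str]


def find_amacrine_runs(
    reconstruction: NeuronReconstruction, synapses: Sequence[SynapseRecord]
) -> list[AmacrineRun]:
    """Maximal runs of consecutive amacrine synapses along dendrites.

    Synapses are attached to their nearest skeleton node, ordered by
    cumulative arc length along each root-to-leaf path, and maximal runs
    of consecutive conventional (amacrine) records are collected per
    path.  Runs repeated across paths sharing a prefix are reported once:
    a run whose member set is contained in another reported run is
    dropped.
    """
    att = attach_synapses(reconstruction, synapses)
    index = reconstruction.node_index()
    for s in synapses:
        if att[s.synapse_id] not in index:
            raise ValueError(f"synapse {s.synapse_id} attached to no node")

    # cumulative arc length from root, per node
    arc: dict[str, float] = {}
    children = reconstruction.children_map()
    stack = [(r.node_id, 0.0) for r in reconstruction.roots()]
    while stack:
        nid, a = stack.pop()
        arc[nid] = a
        n = index[nid]
        for cid in children.get(nid, []):
            c = index[cid]
            step = float(np.hypot(np.hypot(c.x - n.x, c.y - n.y), c.z - n.z))
            stack.append((cid, a + step))

    by_node: dict[str, list[SynapseRecord]] = {}
    for s in synapses:
        by_node.setdefault(att[s.synapse_id], []).append(s)

    # enumerate root-to-leaf paths
    paths: list[list[str]] = []
    for root in reconstruction.roots():
        dfs = [[root.node_id]]
        while dfs:
            path = dfs.pop()
            kids = children.get(path[-1], [])
            if not kids:
                paths.append(path)
            else:
                for cid in sorted(kids):
                    dfs.append(path + [cid])

    runs: list[AmacrineRun] = []
    for pi, path in enumerate(sorted(paths)):
        ordered: list[SynapseRecord] = []
        for nid in path:
            ordered.extend(
                sorted(by_node.get(nid, []), key=lambda s: s.synapse_id)
            )
        ordered.sort(key=lambda s: (arc[att[s.synapse_id]], s.synapse_id))
        current: list[str] = []
        for s in ordered + [None]:  # type: ignore[list-item]
            if s is not None and s.kind == "conventional":
                current.append(s.synapse_id)
            elif current:
                runs.append(AmacrineRun(f"path-{pi:03d}", len(current), current))
                current = []

    # deduplicate runs shared across paths (prefix runs)
    sets = [frozenset(r.synapse_ids) for r in runs]
    keep: list[AmacrineRun] = []
    seen: set[frozenset] = set()
    for i, r in enumerate(runs):
        if sets[i] in seen:
            continue
        if any(i != j and sets[i] < sets[j] for j in range(len(runs))):
            continue
        seen.add(sets[i])
        keep.append(r)
    return keep


@dataclass
class PartnerProfile:
    """Per-presynaptic-partner synapse counts for one postsynaptic cell."""

    partners: list[tuple[str, str, int]]  # (pre_cell_id, pre_type, n_synapses)
    totals_by_type: dict[str, int] = field(default_factory=dict)
    mean_synapses_per_partner: float = 0.0

    @property
    def n_partners(self) -> int:
        return len(self.partners)

    @property
    def n_synapses(self) -> int:
        return sum(n for _, _, n in self.partners)

    def count_histogram(self) -> dict[int, int]:
        """Histogram of per-partner synapse counts: count -> n partners."""
        h: dict[int, int] = {}
        for _, _, n in self.partners:
            h[n] = h.get(n, 0) + 1
        return dict(sorted(h.items()))


def partner_profile(synapses: Sequence[SynapseRecord]) -> PartnerProfile:
    """Per-partner synapse counts, totals by type, and the mean load."""
    counts: dict[str, int] = {}
    types: dict[str, str] = {}
    totals: dict[str, int] = {}
    for s in synapses:
        counts[s.pre_cell_id] = counts.get(s.pre_cell_id, 0) + 1
        types[s.pre_cell_id] = s.pre_type
        totals[s.pre_type] = totals.get(s.pre_type, 0) + 1
    partners = sorted(
        [(pid, types[pid], n) for pid, n in counts.items()],
        key=lambda t: (-t[2], t[0]),
    )
    mean = (sum(counts.values()) / len(counts)) if counts else 0.0
    return PartnerProfile(partners, dict(sorted(totals.items())), mean)


def mean_synapses_per_partner(n_synapses: float, n_partners: float) -> float:
    """Evenly-distributed synapse load per presynaptic partner."""
    if n_partners <= 0:
        raise ValueError("n_partners must be > 0")
    return n_synapses / n_partners


def classification_rate(
    synapses: Optional[Sequence[SynapseRecord]] = None,
    n_classified: Optional[int] = None,
    n_total: Optional[int] = None,
) -> tuple[int, int, float]:
    """(classified, total, percent to 2 dp) for ribbon synapses."""
    if synapses is not None:
        n_total = len(synapses)
        n_classified = sum(1 for s in synapses if s.pre_type != "unclassified")
    if n_total is None or n_classified is None:
        raise ValueError("pass synapses or both counts")
    if n_total == 0:
        raise ValueError("zero total synapses")
    return n_classified, n_total, round(100.0 * n_classified / n_total, 2)


def fisher_exact_2x2(table, alternative: str = "two-sided",
                     method: str = "min-likelihood") -> float:
    """Two-sided Fisher's exact p for a 2×2 contingency table.

    The default two-sided convention sums hypergeometric probabilities of
    tables (with the observed margins) no more likely than the observed
    one; ``method="doubling"`` doubles the smaller one-sided tail instead.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2×2 integer array")
    if t.sum(axis=0).min() == 0 and t.sum(axis=1).min() == 0 and t.sum() == 0:
        raise ValueError("all-zero table")
    if method == "min-likelihood":
        return float(_sstats.fisher_exact(t, alternative=alternative)[1])
    if method != "doubling":
        raise ValueError(f"unknown method {method!r}")
    less = _sstats.fisher_exact(t, alternative="less")[1]
    greater = _sstats.fisher_exact(t, alternative="greater")[1]
    return float(min(1.0, 2.0 * min(less, greater)))


@dataclass
class OverlapReport:
    """Test-cell synapses relative to a reference cell's dendritic hull."""

    hull: HullMetrics
    member_mask: np.ndarray  # True where the synapse falls inside the hull
    distances: np.ndarray  # µm to hull centroid, members only
    shared_partners: dict[str, int] = field(default_factory=dict)  # pre_type -> n

    @property
    def n_members(self) -> int:
        return int(self.member_mask.sum())


def overlap_analysis(
    test_synapses: Sequence[SynapseRecord],
    reference_hull: HullMetrics,
    reference_synapses: Optional[Sequence[SynapseRecord]] = None,
) -> OverlapReport:
    """Classify test synapses against a reference dendritic field.

    Membership is boundary-inclusive point-in-polygon on the x–y hull
    (1e-9 µm tolerance); distances are 2D Euclidean from each member
    synapse to the hull's area centroid.  When the reference cell's own
    synapses are given, shared partners (presynaptic cells contacting
    both cells) are counted by type.
    """
    if reference_hull.area <= 0:
        raise DegenerateGeometryError("reference hull is degenerate")
    poly = Polygon(reference_hull.vertices)
    cx, cy = reference_hull.centroid
    mask = np.array(
        [poly.distance(Point(s.x, s.y)) <= _GEOM_TOL for s in test_synapses],
        dtype=bool,
    )
    dists = np.array(
        [np.hypot(s.x - cx, s.y - cy) for s, m in zip(test_synapses, mask) if m]
    )
    shared: dict[str, int] = {}
    if reference_synapses is not None:
        ref_partners = {s.pre_cell_id for s in reference_synapses}
        seen: set[str] = set()
        for s in test_synapses:
            if s.pre_cell_id in ref_partners and s.pre_cell_id not in seen:
                seen.add(s.pre_cell_id)
                shared[s.pre_type] = shared.get(s.pre_type, 0) + 1
    return OverlapReport(reference_hull, mask, dists, dict(sorted(shared.items())))
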