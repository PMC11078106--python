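"""Domain types for skeletonized reconstructions and synapse tables.

A reconstruction is a forest of annotation disks (nodes) with soma /
dendrite / axon tags; a synapse record links a presynaptic cell to a
postsynaptic cell at a 3D point.  Coordinates are µm, right-handed, with
z increasing from the INL/IPL boundary toward the ganglion-cell layer.
All planar analyses (hulls, density maps, clustering) use x–y only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

CELL_TYPES = (
    "RGC_smooth",
    "RGC_parasol",
    "BC_DB4",
    "BC_DB5",
    "BC_DB6",
    "BC_giant",
    "BC_ON_midget",
    "amacrine",
    "unclassified",
)

#: cell types whose output synapses are ribbon synapses
BIPOLAR_TYPES = ("BC_DB4", "BC_DB5", "BC_DB6", "BC_giant", "BC_ON_midget")

NODE_TAGS = ("soma", "dendrite", "axon")
SYNAPSE_KINDS = ("ribbon", "conventional")


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


class DegenerateGeometryError(ValueError):
    """A geometric operation received degenerate input (e.g. collinear points)."""


@dataclass(frozen=True)
class AnnotationNode:
    """One annotation disk on a skeleton."""

    node_id: str
    cell_id: str
    x: float
    y: float
    z: float
    radius: float
    parent_id: Optional[str]  # None at roots
    tag: str  # soma | dendrite | axon

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(
                f"node {self.node_id}: radius must be > 0, got {self.radius}"
            )
        if self.tag not in NODE_TAGS:
            raise ValidationError(f"node {self.node_id}: unknown tag {self.tag!r}")
        for name in ("x", "y", "z"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"node {self.node_id}: non-finite {name}")


@dataclass
class NeuronReconstruction:
    """A skeletonized cell: ordered annotation nodes forming a rooted forest."""

    cell_id: str
    cell_type: str
    nodes: list[AnnotationNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(
                f"cell {self.cell_id}: unknown cell_type {self.cell_type!r}"
            )
        self.validate()

    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValidationError(f"cell {self.cell_id}: duplicate node_ids {sorted(dups)}")
        id_set = set(ids)
        for n in self.nodes:
            if n.cell_id != self.cell_id:
                raise ValidationError(
                    f"cell {self.cell_id}: node {n.node_id} belongs to {n.cell_id}"
                )
            if n.parent_id is not None and n.parent_id not in id_set:
                raise ValidationError(
                    f"cell {self.cell_id}: node {n.node_id} has unknown parent "
                    f"{n.parent_id}"
                )
        if not any(n.tag == "soma" for n in self.nodes):
            raise ValidationError(f"cell {self.cell_id}: no soma-tagged node")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = {n.node_id: n.parent_id for n in self.nodes}
        state: dict[str, int] = {}  # 0 visiting, 1 done
        for start in parent:
            path = []
            cur: Optional[str] = start
            while cur is not None and state.get(cur) != 1:
                if state.get(cur) == 0:
                    raise ValidationError(
                        f"cell {self.cell_id}: cycle in parent links at {cur}"
                    )
                state[cur] = 0
                path.append(cur)
                cur = parent[cur]
            for nid in path:
                state[nid] = 1

    # -- convenience accessors ------------------------------------------------

    def nodes_by_tag(self, *tags: str) -> list[AnnotationNode]:
        return [n for n in self.nodes if n.tag in tags]

    def dendrite_xy(self) -> np.ndarray:
        """x–y coordinates of dendrite-tagged nodes, (n, 2)."""
        d = self.nodes_by_tag("dendrite")
        return np.array([[n.x, n.y] for n in d], dtype=float).reshape(len(d), 2)

    def node_index(self) -> dict[str, AnnotationNode]:
        return {n.node_id: n for n in self.nodes}

    def roots(self) -> list[AnnotationNode]:
        return [n for n in self.nodes if n.parent_id is None]

    def children_map(self) -> dict[Optional[str], list[str]]:
        ch: dict[Optional[str], list[str]] = {}
        for n in self.nodes:
            ch.setdefault(n.parent_id, []).append(n.node_id)
        return ch


@dataclass(frozen=True)
class SynapseRecord:
    """One annotated synaptic contact."""

    synapse_id: str
    pre_cell_id: str
    post_cell_id: str
    kind: str  # ribbon | conventional
    x: float
    y: float
    z: float
    pre_type: str = "unclassified"

    def __post_init__(self) -> None:
        if self.kind not in SYNAPSE_KINDS:
            raise ValidationError(f"synapse {self.synapse_id}: unknown kind {self.kind!r}")
        if self.pre_type not in CELL_TYPES:
            raise ValidationError(
                f"synapse {self.synapse_id}: unknown pre_type {self.pre_type!r}"
            )
        for name in ("x", "y", "z"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"synapse {self.synapse_id}: non-finite {name}")
        # ribbon synapses come from bipolar cells (when the type is known)
        if self.pre_type != "unclassified":
            is_bipolar = self.pre_type in BIPOLAR_TYPES
            if (self.kind == "ribbon") != is_bipolar:
                raise ValidationError(
                    f"synapse {self.synapse_id}: kind {self.kind} inconsistent with "
                    f"pre_type {self.pre_type}"
                )

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class IPLBoundaries:
    """Constant-plane IPL boundary model: z of INL/IPL (0 %) and IPL/GCL (100 %)."""

    inl_ipl_z: float
    ipl_gcl_z: float

    def __post_init__(self) -> None:
        if self.inl_ipl_z == self.ipl_gcl_z:
            raise ValidationError("IPL boundaries coincide")


@dataclass
class Dataset:
    """Reconstructions plus their synapse table and layer boundaries."""

    reconstructions: list[NeuronReconstruction]
    synapses: list[SynapseRecord]
    ipl_boundaries: Optional[IPLBoundaries] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        known = {r.cell_id for r in self.reconstructions}
        if len(known) != len(self.reconstructions):
            raise ValidationError("duplicate cell_ids among reconstructions")
        missing = sorted({s.post_cell_id for s in self.synapses} - known)
        if missing:
            raise ValidationError(
                f"synapses reference unknown post_cell_ids: {missing}"
            )
        sids = [s.synapse_id for s in self.synapses]
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate synapse_ids")

    def cell(self, cell_id: str) -> NeuronReconstruction:
        for r in self.reconstructions:
            if r.cell_id == cell_id:
                return r
        raise KeyError(f"unknown cell id {cell_id!r}")


def subset_synapses(
    dataset: Dataset,
    post_cell_id: str,
    kind: Optional[str] = None,
    pre_type: Optional[str] = None,
) -> list[SynapseRecord]:
    """Synapses onto one cell, optionally filtered by kind and presynaptic type.

    Filters are conjunctive; output order is stable by synapse_id.
    """
    dataset.cell(post_cell_id)  # raises KeyError for unknown cells
    out = [
        s
        for s in dataset.synapses
        if s.post_cell_id == post_cell_id
        and (kind is None or s.kind == kind)
        and (pre_type is None or s.pre_type == pre_type)
    ]
    return sorted(out, key=lambda s: s.synapse_id)


def attach_synapses(
    reconstruction: NeuronReconstruction, synapses: Iterable[SynapseRecord]
) -> dict[str, str]:
    """Attach each synapse to its nearest skeleton node (3D Euclidean).

    Ties are broken toward the lower node_id (string order).  Returns
    synapse_id -> node_id.
    """
    nodes = sorted(reconstruction.nodes, key=lambda n: n.node_id)
    if not nodes:
        raise ValidationError(f"cell {reconstruction.cell_id} has no nodes")
    coords = np.array([[n.x, n.y, n.z] for n in nodes])
    out: dict[str, str] = {}
    for s in synapses:
        d2 = np.sum((coords - np.array([s.x, s.y, s.z])) ** 2, axis=1)
        out[s.synapse_id] = nodes[int(np.argmin(d2))].node_id  # argmin = first min
    return out
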