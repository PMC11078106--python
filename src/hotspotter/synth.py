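"""Synthetic reconstructions and synapse tables with planted ground truth.

The generator emulates the statistical structure of the EM reconstructions
the analysis targets: a large, sparse, radiate retinal ganglion cell
(dendritic field ~150 µm across) versus small, dense, tortuous cells
(~57 µm across) co-stratifying in the IPL; an amacrine:bipolar synapse
ratio of ~1.6:1; and bipolar (ribbon) synapses drawn either homogeneously
along the dendritic cable or from a planted K-component Gaussian intensity
— the hotspot oracle every downstream stage is verified against.

Skeleton growth is deliberately simple: fixed-length segments whose
direction is the parent direction plus small angular noise, bifurcating
with a per-segment probability, terminated at the field radius.  Synapses
are placed by rejection sampling over dendrite nodes, so they always lie
on the cable; this decouples synapse clustering from dendrite density.

Seeds are explicit everywhere; there is no hidden global RNG state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import (
    AnnotationNode,
    BIPOLAR_TYPES,
    Dataset,
    IPLBoundaries,
    NeuronReconstruction,
    SynapseRecord,
)


@dataclass(frozen=True)
class MixtureComponent:
    """One planted Gaussian intensity component (isotropic, sd in µm)."""

    weight: float
    center: tuple[float, float]
    sd: float


@dataclass
class SkeletonConfig:
    """Parameters of the segment-growth skeleton generator (lengths in µm)."""

    cell_id: str = "cell-1"
    cell_type: str = "RGC_smooth"
    n_primary_dendrites: int = 12
    field_radius: float = 78.0  # realized hull diameter ≈ 153 µm
    segment_length: float = 2.0
    branch_prob: float = 0.15
    soma_radius: float = 7.25
    stratification_z: float = 26.0
    z_jitter_sd: float = 1.0
    soma_xy: tuple[float, float] = (0.0, 0.0)
    angle_noise_sd: float = 0.12  # radians per segment
    dendrite_radius: float = 0.35
    max_nodes: int = 16000  # hard cap against runaway branching
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_radius <= 0:
            raise ValueError("field_radius must be > 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.segment_length > self.field_radius:
            raise ValueError(
                f"segment_length ({self.segment_length}) exceeds field_radius "
                f"({self.field_radius}): impossible geometry"
            )


@dataclass
class SynapseModel:
    """Parameters of the synapse generator.

    ``bipolar_spatial`` is ``"homogeneous"`` (uniform over cable) or
    ``"mixture"`` (planted Gaussian hotspots in ``mixture_components``).
    ``type_proportions`` gives presynaptic-type probabilities for bipolar
    (ribbon) records; amacrine records are always typed ``amacrine``.
    ``mean_synapses_per_partner`` sets the size of the per-type partner
    pool presynaptic ids are drawn from.
    """

    n_synapses: int = 330
    amacrine_fraction: float = 1.6 / 2.6
    bipolar_spatial: str = "mixture"
    mixture_components: list[MixtureComponent] = field(default_factory=list)
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {"BC_DB5": 0.55, "BC_DB4": 0.30, "BC_giant": 0.15}
    )
    mean_synapses_per_partner: float = 1.8
    position_jitter_sd: float = 1.5  # µm; synapses sit on the membrane near a node
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amacrine_fraction <= 1.0:
            raise ValueError("amacrine_fraction must be in [0, 1]")
        if self.bipolar_spatial not in ("homogeneous", "mixture"):
            raise ValueError(f"unknown bipolar_spatial {self.bipolar_spatial!r}")
        tp = sum(self.type_proportions.values())
        if self.type_proportions and abs(tp - 1.0) > 1e-9:
            raise ValueError(f"type_proportions sum to {tp}, not 1")
        if self.bipolar_spatial == "mixture" and self.mixture_components:
            w = sum(c.weight for c in self.mixture_components)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"mixture weights sum to {w}, not 1")
        for t in self.type_proportions:
            if t not in BIPOLAR_TYPES and t != "unclassified":
                raise ValueError(f"type_proportions key {t!r} is not a bipolar type")


def default_hotspot_mixture(
    n_components: int = 4, ring_radius: float = 45.0, sd: float = 8.0
) -> list[MixtureComponent]:
    """Equal-weight isotropic hotspots on a ring (adjacent centers ≥60 µm apart
    for the default 4-on-a-45-µm-ring geometry)."""
    out = []
    for k in range(n_components):
        a = math.pi / n_components + 2 * math.pi * k / n_components
        out.append(
            MixtureComponent(
                weight=1.0 / n_components,
                center=(ring_radius * math.cos(a), ring_radius * math.sin(a)),
                sd=sd,
            )
        )
    return out


def smooth_config(seed: int = 0, **overrides) -> SkeletonConfig:
    """A sparse radiate cell with a ~153 µm dendritic field."""
    return replace(SkeletonConfig(seed=seed), **overrides)


def parasol_config(cell_id: str, soma_xy: tuple[float, float], seed: int = 0,
                   **overrides) -> SkeletonConfig:
    """A small dense tortuous cell with a ~57 µm dendritic field."""
    base = SkeletonConfig(
        cell_id=cell_id,
        cell_type="RGC_parasol",
        n_primary_dendrites=5,
        field_radius=28.5,
        segment_length=1.5,
        branch_prob=0.18,
        soma_radius=7.45,
        stratification_z=26.0,
        z_jitter_sd=1.0,
        soma_xy=soma_xy,
        angle_noise_sd=0.45,
        max_nodes=8000,
        seed=seed,
    )
    return replace(base, **overrides)


def parasol_synapse_model(seed: int = 0, **overrides) -> SynapseModel:
    """Homogeneous bipolar input with parasol-like type proportions."""
    base = SynapseModel(
        n_synapses=485,
        amacrine_fraction=1.6 / 2.6,
        bipolar_spatial="homogeneous",
        mixture_components=[],
        type_proportions={
            "BC_DB4": 0.50, "BC_ON_midget": 0.256, "BC_DB5": 0.184, "BC_giant": 0.06,
        },
        mean_synapses_per_partner=4.57,
        seed=seed,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# skeleton growth

def generate_skeleton(config: SkeletonConfig) -> NeuronReconstruction:
    """Grow a rooted dendritic tree by fixed-length segments.

    The soma node is the root and has exactly ``n_primary_dendrites``
    children; every node lies within ``field_radius`` of the soma in x–y.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cx, cy = config.soma_xy
    nodes: list[AnnotationNode] = []
    counter = 0

    def new_node(x, y, z, radius, parent, tag) -> AnnotationNode:
        nonlocal counter
        n = AnnotationNode(
            node_id=f"{config.cell_id}-n{counter:05d}",
            cell_id=config.cell_id,
            x=float(x), y=float(y), z=float(z),
            radius=float(radius), parent_id=parent, tag=tag,
        )
        counter += 1
        nodes.append(n)
        return n

    soma = new_node(cx, cy, config.stratification_z, config.soma_radius, None, "soma")

    # active tips: (x, y, direction angle, parent node id, steps taken)
    tips: list[tuple[float, float, float, str, int]] = []
    base = rng.uniform(0, 2 * math.pi)
    for k in range(config.n_primary_dendrites):
        ang = base + 2 * math.pi * k / config.n_primary_dendrites
        x = cx + config.soma_radius * math.cos(ang)
        y = cy + config.soma_radius * math.sin(ang)
        z = config.stratification_z + rng.normal(0, config.z_jitter_sd)
        n = new_node(x, y, z, config.dendrite_radius, soma.node_id, "dendrite")
        tips.append((x, y, ang, n.node_id, 0))

    # a tip that wanders without reaching the field edge is retired after a
    # generous step budget, so growth always terminates
    max_steps = int(math.ceil(3.0 * config.field_radius / config.segment_length))
    while tips and counter < config.max_nodes:
        x, y, ang, parent, steps = tips.pop(0)
        if steps >= max_steps:
            continue
        ang = ang + rng.normal(0, config.angle_noise_sd)
        nx = x + config.segment_length * math.cos(ang)
        ny = y + config.segment_length * math.sin(ang)
        if math.hypot(nx - cx, ny - cy) > config.field_radius:
            continue  # tip reached the field edge
        z = config.stratification_z + rng.normal(0, config.z_jitter_sd)
        n = new_node(nx, ny, z, config.dendrite_radius, parent, "dendrite")
        if rng.uniform() < config.branch_prob:
            split = rng.uniform(0.3, 0.7)
            tips.append((nx, ny, ang - split, n.node_id, steps + 1))
            tips.append((nx, ny, ang + split, n.node_id, steps + 1))
        else:
            tips.append((nx, ny, ang, n.node_id, steps + 1))

    return NeuronReconstruction(config.cell_id, config.cell_type, nodes)


# ---------------------------------------------------------------------------
# synapse placement

def _mixture_intensity(xy: np.ndarray, components: Sequence[MixtureComponent]) -> np.ndarray:
    out = np.zeros(len(xy))
    for c in components:
        d2 = np.sum((xy - np.asarray(c.center)) ** 2, axis=1)
        out += c.weight * np.exp(-d2 / (2.0 * c.sd**2)) / (2 * math.pi * c.sd**2)
    return out


#: grid size (µm) for the local cable-density estimate used to convert the
#: planted areal intensity into per-node acceptance weights
_DENSITY_BIN_UM = 6.0


def _local_cable_density(xy: np.ndarray) -> np.ndarray:
    """Nodes per grid cell at each node's location (coarse 2D histogram)."""
    ix = np.floor(xy[:, 0] / _DENSITY_BIN_UM).astype(int)
    iy = np.floor(xy[:, 1] / _DENSITY_BIN_UM).astype(int)
    counts: dict[tuple[int, int], int] = {}
    for key in zip(ix.tolist(), iy.tolist()):
        counts[key] = counts.get(key, 0) + 1
    return np.array([counts[k] for k in zip(ix.tolist(), iy.tolist())], dtype=float)


def place_synapses(
    skeleton: NeuronReconstruction,
    model: SynapseModel,
    synapse_prefix: Optional[str] = None,
    partner_prefix: Optional[str] = None,
) -> list[SynapseRecord]:
    """Place exactly ``model.n_synapses`` synapses on dendrite nodes.

    Each synapse is independently amacrine (conventional) with probability
    ``amacrine_fraction``, otherwise bipolar (ribbon).  Amacrine synapses
    are uniform over dendrite nodes; bipolar synapses are drawn by
    rejection sampling with acceptance proportional to the planted mixture
    intensity at the node (homogeneous = uniform over cable).  Presynaptic
    ids come from per-type partner pools sized by
    ``mean_synapses_per_partner``.
    """
    dend = skeleton.nodes_by_tag("dendrite")
    if not dend:
        raise ValueError(f"cell {skeleton.cell_id} has no dendrite nodes")
    rng = np.random.default_rng(model.seed)
    xy = np.array([[n.x, n.y] for n in dend])

    use_mixture = model.bipolar_spatial == "mixture" and model.mixture_components
    if use_mixture:
        # the planted mixture is an areal intensity: divide by the local cable
        # density so cable-rich regions are not over-sampled (a candidate node
        # is uniform over nodes, so acceptance ∝ intensity per unit cable)
        weight = _mixture_intensity(xy, model.mixture_components)
        weight = weight / _local_cable_density(xy)
        # winsorize so a single node in a near-empty grid cell cannot make
        # every other node's acceptance (and hence sampling) vanishingly slow
        weight = np.minimum(weight, np.percentile(weight, 99.0))
        peak = weight.max()
        if peak <= 0:
            warnings.warn(
                f"cell {skeleton.cell_id}: planted mixture has zero intensity on "
                "the skeleton; falling back to uniform placement"
            )
            use_mixture = False
        else:
            accept = weight / peak

    is_am = rng.uniform(size=model.n_synapses) < model.amacrine_fraction
    types = list(model.type_proportions) or ["unclassified"]
    probs = np.array([model.type_proportions.get(t, 1.0) for t in types])
    probs = probs / probs.sum()

    # partner pools: expected count per type / mean synapses per partner
    n_bip_expected = model.n_synapses * (1 - model.amacrine_fraction)
    pools: dict[str, list[str]] = {}
    ppfx = partner_prefix or f"{skeleton.cell_id}-pre"
    for t, p in zip(types, probs):
        size = max(1, round(n_bip_expected * p / model.mean_synapses_per_partner))
        pools[t] = [f"{ppfx}-{t}-{i:04d}" for i in range(size)]
    n_am_pool = max(1, round(
        model.n_synapses * model.amacrine_fraction / model.mean_synapses_per_partner
    ))
    pools["amacrine"] = [f"{ppfx}-amacrine-{i:04d}" for i in range(n_am_pool)]

    spfx = synapse_prefix or f"{skeleton.cell_id}-syn"
    records: list[SynapseRecord] = []
    max_attempts = 1000
    warned = False
    for i in range(model.n_synapses):
        if is_am[i]:
            node = dend[int(rng.integers(len(dend)))]
            pre_type, kind = "amacrine", "conventional"
        else:
            if use_mixture:
                node = None
                for _ in range(max_attempts):
                    j = int(rng.integers(len(dend)))
                    if rng.uniform() < accept[j]:
                        node = dend[j]
                        break
                if node is None:
                    if not warned:
                        warnings.warn(
                            f"cell {skeleton.cell_id}: mixture rejection sampling "
                            f"exhausted {max_attempts} attempts; using uniform draw"
                        )
                        warned = True
                    node = dend[int(rng.integers(len(dend)))]
            else:
                node = dend[int(rng.integers(len(dend)))]
            pre_type = types[int(rng.choice(len(types), p=probs))]
            kind = "ribbon"
        pool = pools["amacrine" if pre_type == "amacrine" else pre_type] \
            if pre_type != "unclassified" else pools["unclassified"] \
            if "unclassified" in pools else None
        if pool is None:
            pre_cell = f"{ppfx}-unclassified-{i:04d}"
        else:
            pre_cell = pool[int(rng.integers(len(pool)))]
        jx, jy = rng.normal(0, model.position_jitter_sd, size=2)
        records.append(
            SynapseRecord(
                synapse_id=f"{spfx}-{i:05d}",
                pre_cell_id=pre_cell,
                post_cell_id=skeleton.cell_id,
                kind=kind,
                x=float(node.x + jx), y=float(node.y + jy), z=node.z,
                pre_type=pre_type,
            )
        )
    return records


# ---------------------------------------------------------------------------
# paired scenes

def generate_paired_scene(
    smooth_cfg: Optional[SkeletonConfig] = None,
    parasol_cfgs: Optional[Sequence[SkeletonConfig]] = None,
    model: Optional[SynapseModel] = None,
    parasol_model: Optional[SynapseModel] = None,
    seed: int = 0,
) -> tuple[Dataset, dict]:
    """One large sparse cell plus small dense cells inside its field.

    Emulates the geometry of co-stratifying parasol cells located within
    the smooth cell's dendritic field.  Returns the dataset and a
    ground-truth dict (planted component centers verbatim from config,
    cell roles, seeds) suitable for writing as ``truth.json``.
    """
    if smooth_cfg is None:
        smooth_cfg = smooth_config(seed=seed, cell_id="smooth-1")
    if model is None:
        model = SynapseModel(
            seed=seed + 1, mixture_components=default_hotspot_mixture()
        )
    if parasol_cfgs is None:
        ring = 0.55 * smooth_cfg.field_radius
        parasol_cfgs = [
            parasol_config(
                f"parasol-{k + 1}",
                soma_xy=(
                    smooth_cfg.soma_xy[0] + ring * math.cos(2 * math.pi * k / 3),
                    smooth_cfg.soma_xy[1] + ring * math.sin(2 * math.pi * k / 3),
                ),
                seed=seed + 10 + k,
            )
            for k in range(3)
        ]
    if parasol_model is None:
        parasol_model = parasol_synapse_model(seed=seed + 2)

    ids = [smooth_cfg.cell_id] + [c.cell_id for c in parasol_cfgs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"overlapping cell_ids: {ids}")
    for c in parasol_cfgs:
        d = math.hypot(c.soma_xy[0] - smooth_cfg.soma_xy[0],
                       c.soma_xy[1] - smooth_cfg.soma_xy[1])
        if d > smooth_cfg.field_radius:
            raise ValueError(
                f"parasol {c.cell_id} soma lies outside the smooth field "
                f"({d:.1f} > {smooth_cfg.field_radius} µm)"
            )

    recs = [generate_skeleton(smooth_cfg)]
    synapses = place_synapses(recs[0], model)
    for k, cfg in enumerate(parasol_cfgs):
        rec = generate_skeleton(cfg)
        recs.append(rec)
        pm = replace(parasol_model, seed=parasol_model.seed + 100 * (k + 1))
        synapses.extend(place_synapses(rec, pm))

    depth = smooth_cfg.stratification_z  # plant stratification at 65 % depth
    ipl = IPLBoundaries(inl_ipl_z=0.0, ipl_gcl_z=depth / 0.65)
    dataset = Dataset(recs, synapses, ipl)
    truth = {
        "roles": {smooth_cfg.cell_id: "smooth",
                  **{c.cell_id: "parasol" for c in parasol_cfgs}},
        "bipolar_spatial": model.bipolar_spatial,
        "planted_components": [
            {"weight": c.weight, "center": list(c.center), "sd": c.sd}
            for c in (model.mixture_components or [])
        ],
        "amacrine_fraction": model.amacrine_fraction,
        "type_proportions": model.type_proportions,
        "seeds": {"smooth_skeleton": smooth_cfg.seed, "smooth_synapses": model.seed,
                  "parasol_skeletons": [c.seed for c in parasol_cfgs],
                  "parasol_synapses": parasol_model.seed},
    }
    return dataset, truth
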