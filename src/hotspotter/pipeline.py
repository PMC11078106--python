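"""End-to-end orchestration: morphometry → density → clustering → stats →
overlap, with a validated, reproducible report.

Each stage draws from its own RNG stream derived from the master seed by
a stable hash of the stage name, so adding a stage never perturbs another
stage's draws.  A failed stage is recorded in ``Report.errors`` and the
remaining stages still run.  The report schema is published as JSON
Schema (``Report.model_json_schema()``) and written next to the report.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .clustering import cluster_composition, flag_outliers, select_components
from .density import DensityMap, default_bin_size, density_map, write_map
from .model import Dataset, subset_synapses
from .morphometry import dendritic_field_hull, depth_profile, soma_diameter
from .stats import (
    amacrine_probability,
    classification_rate,
    find_amacrine_runs,
    overlap_analysis,
    partner_profile,
    run_probability,
)


class AnalysisConfig(BaseModel):
    """Pipeline configuration; ``seed`` governs every stochastic step."""

    roles: dict[str, str]  # cell_id -> smooth | parasol
    seed: int
    smoothing: float = 1.0  # Whittaker λ
    bin_size_synapse: Optional[float] = None  # None = auto from field diameter
    bin_size_dendrite: Optional[float] = None
    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 10
    outlier_threshold: float = 3.0
    min_run_length: int = 5
    output_dir: Optional[str] = None

    def model_post_init(self, _ctx) -> None:
        if self.k_min < 2:
            raise ValueError("k_min must be ≥ 2")
        bad = {r for r in self.roles.values()} - {"smooth", "parasol"}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage RNG seed derived from the master seed."""
        return zlib.crc32(f"{stage}:{self.seed}".encode()) % (2**31)


class CellMorphometry(BaseModel):
    hull_area: float
    field_diameter: float
    centroid: tuple[float, float]
    soma_diameter: float
    mean_depth: Optional[float] = None
    mode_depth: Optional[float] = None


class ClusterReport(BaseModel):
    cell_id: str
    selected_k: int
    ch_by_k: dict[int, float]
    low_contrast: bool
    components: list[dict]  # mean, sd, weight per component
    n_outliers: int
    composition: dict[int, dict[str, float]]
    assignments: list[int]
    outlier_synapse_ids: list[str]


class SynapseStats(BaseModel):
    n_total: int
    n_amacrine: int
    n_bipolar: int
    amacrine_probability: float
    classification: Optional[dict] = None
    runs_at_least_min: int
    longest_run: int
    run_null_probabilities: dict[int, float]
    partner_mean: float
    partner_count: int
    partner_histogram: dict[int, int]
    totals_by_type: dict[str, int]


class OverlapSummary(BaseModel):
    test_cell: str
    reference_cell: str
    n_test_synapses: int
    n_inside: int
    mean_distance_to_center: Optional[float] = None
    shared_partners: dict[str, int]


class Report(BaseModel):
    """Structured output of one pipeline run; every number is traceable to
    a single library operation."""

    morphometry: dict[str, CellMorphometry] = Field(default_factory=dict)
    density_maps: dict[str, dict] = Field(default_factory=dict)
    clusters: dict[str, ClusterReport] = Field(default_factory=dict)
    synapse_stats: dict[str, SynapseStats] = Field(default_factory=dict)
    overlap: list[OverlapSummary] = Field(default_factory=list)
    errors: dict[str, str] = Field(default_factory=dict)
    provenance: dict = Field(default_factory=dict)


def _morphometry_stage(dataset: Dataset, config: AnalysisConfig, report: Report) -> None:
    for cell_id in config.roles:
        rec = dataset.cell(cell_id)
        hull = dendritic_field_hull(rec)
        entry = CellMorphometry(
            hull_area=hull.area,
            field_diameter=hull.equivalent_diameter,
            centroid=hull.centroid,
            soma_diameter=soma_diameter(rec),
        )
        if dataset.ipl_boundaries is not None:
            z = np.array([n.z for n in rec.nodes_by_tag("dendrite")])
            prof = depth_profile(z, dataset.ipl_boundaries)
            entry.mean_depth = prof.mean_depth
            entry.mode_depth = prof.mode_depth
        report.morphometry[cell_id] = entry


def _density_stage(dataset: Dataset, config: AnalysisConfig, report: Report) -> None:
    out = Path(config.output_dir) / "maps" if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    for cell_id in config.roles:
        rec = dataset.cell(cell_id)
        diam = report.morphometry[cell_id].field_diameter
        maps: dict[str, DensityMap] = {}
        syn = subset_synapses(dataset, cell_id)
        if syn:
            bs = config.bin_size_synapse or default_bin_size("synapse", diam)
            maps["synapses"] = density_map(
                np.array([[s.x, s.y] for s in syn]), bs, config.smoothing
            )
        dxy = rec.dendrite_xy()
        if len(dxy):
            bd = config.bin_size_dendrite or default_bin_size("dendrite", diam)
            maps["dendrites"] = density_map(dxy, bd, config.smoothing)
        report.density_maps[cell_id] = {
            what: {
                "bin_size": m.bin_size,
                "shape": list(m.values.shape),
                "n_points": m.n_points,
                "total_mass": float(m.values.sum()),
            }
            for what, m in maps.items()
        }
        if out:
            for what, m in maps.items():
                write_map(m, out / f"{cell_id}_{what}.txt")


def _clustering_stage(dataset: Dataset, config: AnalysisConfig, report: Report) -> None:
    smooth_ids = [c for c, r in config.roles.items() if r == "smooth"]
    if not smooth_ids:
        report.errors["clustering"] = "skipped: no smooth-role cell in config"
        return
    seed = config.stage_seed("clustering")
    for cell_id in smooth_ids:
        ribbon = subset_synapses(dataset, cell_id, kind="ribbon")
        pts = np.array([[s.x, s.y] for s in ribbon])
        model, ch_by_k = select_components(
            pts, config.k_min, config.k_max, config.n_restarts, seed
        )
        flag_outliers(pts, model, config.outlier_threshold)
        comp = cluster_composition(ribbon, model)
        report.clusters[cell_id] = ClusterReport(
            cell_id=cell_id,
            selected_k=model.K,
            ch_by_k={k: (v if np.isfinite(v) else float("nan")) for k, v in ch_by_k.items()},
            low_contrast=getattr(model, "low_contrast", False),
            components=[
                {"mean": c.mean.tolist(), "sd": sd, "weight": c.weight}
                for c, sd in zip(model.components, model.component_sds())
            ],
            n_outliers=int(model.outlier_mask.sum()),
            composition=comp,
            assignments=[int(a) for a in model.assignments],
            outlier_synapse_ids=[
                s.synapse_id for s, o in zip(ribbon, model.outlier_mask) if o
            ],
        )


def _stats_stage(dataset: Dataset, config: AnalysisConfig, report: Report) -> None:
    for cell_id in config.roles:
        rec = dataset.cell(cell_id)
        syn = subset_synapses(dataset, cell_id)
        if not syn:
            continue
        ribbon = [s for s in syn if s.kind == "ribbon"]
        p = amacrine_probability(syn)
        runs = find_amacrine_runs(rec, syn)
        longest = max((r.length for r in runs), default=0)
        prof = partner_profile(ribbon)
        cls = None
        if ribbon:
            n_c, n_t, pct = classification_rate(ribbon)
            cls = {"n_classified": n_c, "n_total": n_t, "percent": pct}
        report.synapse_stats[cell_id] = SynapseStats(
            n_total=len(syn),
            n_amacrine=len(syn) - len(ribbon),
            n_bipolar=len(ribbon),
            amacrine_probability=p,
            classification=cls,
            runs_at_least_min=sum(1 for r in runs if r.length >= config.min_run_length),
            longest_run=longest,
            run_null_probabilities={
                n: run_probability(p, n)
                for n in sorted({config.min_run_length, longest} - {0})
            },
            partner_mean=prof.mean_synapses_per_partner,
            partner_count=prof.n_partners,
            partner_histogram=prof.count_histogram(),
            totals_by_type=prof.totals_by_type,
        )


def _overlap_stage(dataset: Dataset, config: AnalysisConfig, report: Report) -> None:
    smooth_ids = [c for c, r in config.roles.items() if r == "smooth"]
    parasol_ids = [c for c, r in config.roles.items() if r == "parasol"]
    for s_id in smooth_ids:
        test = subset_synapses(dataset, s_id, kind="ribbon")
        for p_id in parasol_ids:
            hull = dendritic_field_hull(dataset.cell(p_id))
            ref_syn = subset_synapses(dataset, p_id, kind="ribbon")
            rep = overlap_analysis(test, hull, ref_syn)
            report.overlap.append(
                OverlapSummary(
                    test_cell=s_id,
                    reference_cell=p_id,
                    n_test_synapses=len(test),
                    n_inside=rep.n_members,
                    mean_distance_to_center=(
                        float(rep.distances.mean()) if rep.n_members else None
                    ),
                    shared_partners=rep.shared_partners,
                )
            )


_STAGES = [
    ("morphometry", _morphometry_stage),
    ("density", _density_stage),
    ("clustering", _clustering_stage),
    ("stats", _stats_stage),
    ("overlap", _overlap_stage),
]


def run_pipeline(dataset: Dataset, config: AnalysisConfig) -> Report:
    """Run all stages in fixed order; deterministic given ``config.seed``.

    A stage that raises is recorded under ``report.errors`` and later
    stages still run (later stages that depend on its output may record
    their own errors).
    """
    report = Report()
    for name, fn in _STAGES:
        try:
            fn(dataset, config, report)
        except Exception as exc:  # partial-failure isolation
            report.errors.setdefault(name, f"{type(exc).__name__}: {exc}")
    cfg_json = config.model_dump_json()
    report.provenance = {
        "package": "hotspotter",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {name: config.stage_seed(name) for name, _ in _STAGES},
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.model_dump_json(indent=2) + "\n")
        (out / "report.schema.json").write_text(
            json.dumps(Report.model_json_schema(), indent=2) + "\n"
        )
    return report


class GroupSummary(BaseModel):
    mean: float
    sd: float  # sample sd (n−1); 0 with single=True when n = 1
    n: int
    single: bool = False


def summarize_group(
    reports: Sequence[Report], metric: str, role_cells: Optional[Sequence[str]] = None
) -> GroupSummary:
    """mean ± sample sd of a per-cell morphometry metric across reports.

    ``metric`` is a :class:`CellMorphometry` field name; ``role_cells``
    optionally restricts which cells contribute.
    """
    if not reports:
        raise ValueError("need at least one report")
    if metric not in CellMorphometry.model_fields:
        raise KeyError(f"unknown metric {metric!r}")
    values = []
    for rep in reports:
        for cell_id, m in rep.morphometry.items():
            if role_cells is not None and cell_id not in role_cells:
                continue
            v = getattr(m, metric)
            if v is not None:
                values.append(float(v))
    if not values:
        raise ValueError(f"metric {metric!r} absent from all reports")
    arr = np.asarray(values)
    if len(arr) == 1:
        return GroupSummary(mean=float(arr[0]), sd=0.0, n=1, single=True)
    return GroupSummary(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(arr)
    )
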