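"""Readers and writers for the CSV dataset schema and SWC export.

Schema (all files UTF-8 CSV with a header row):

* ``nodes.csv``    — cell_id,node_id,parent_id,x_um,y_um,z_um,radius_um,tag
* ``cells.csv``    — cell_id,cell_type
* ``synapses.csv`` — synapse_id,pre_cell_id,post_cell_id,kind,x_um,y_um,z_um,pre_type
* ``ipl.json``     — {"inl_ipl_z": float, "ipl_gcl_z": float}

``parent_id`` is empty at roots.  Writing then loading reproduces the
dataset field-for-field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (
    AnnotationNode,
    Dataset,
    IPLBoundaries,
    NeuronReconstruction,
    SynapseRecord,
    ValidationError,
)

NODE_COLUMNS = ["cell_id", "node_id", "parent_id", "x_um", "y_um", "z_um", "radius_um", "tag"]
CELL_COLUMNS = ["cell_id", "cell_type"]
SYNAPSE_COLUMNS = [
    "synapse_id", "pre_cell_id", "post_cell_id", "kind", "x_um", "y_um", "z_um", "pre_type",
]

SWC_TYPE_CODES = {"soma": 1, "axon": 2, "dendrite": 3}


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed file
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _as_float(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    try:
        return df[col].astype(float)
    except ValueError as exc:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValidationError(
            f"{path}: line {bad + 2}: column {col!r} is not numeric "
            f"({df[col].iloc[bad]!r})"
        ) from exc


def load_dataset(directory: Union[str, Path]) -> Dataset:
    """Load a dataset from ``nodes.csv``/``cells.csv``/``synapses.csv``/``ipl.json``.

    Raises :class:`ValidationError` naming the file and line for malformed
    rows, and listing the offending ids for unresolved cross-references.
    """
    directory = Path(directory)
    cells_df = _read_csv(directory / "cells.csv", CELL_COLUMNS)
    nodes_df = _read_csv(directory / "nodes.csv", NODE_COLUMNS)

    for col in ("x_um", "y_um", "z_um", "radius_um"):
        nodes_df[col] = _as_float(nodes_df, col, directory / "nodes.csv")

    cell_types = dict(zip(cells_df["cell_id"], cells_df["cell_type"]))
    recs: list[NeuronReconstruction] = []
    for cell_id, group in nodes_df.groupby("cell_id", sort=False):
        if cell_id not in cell_types:
            raise ValidationError(f"nodes.csv: cell {cell_id!r} absent from cells.csv")
        nodes = [
            AnnotationNode(
                node_id=r.node_id,
                cell_id=r.cell_id,
                x=r.x_um,
                y=r.y_um,
                z=r.z_um,
                radius=r.radius_um,
                parent_id=(r.parent_id or None),
                tag=r.tag,
            )
            for r in group.itertuples(index=False)
        ]
        recs.append(NeuronReconstruction(cell_id, cell_types[cell_id], nodes))
    # cells listed without nodes are still part of the dataset (empty cells are
    # invalid per the soma invariant, so require nodes for every listed cell)
    nodeless = sorted(set(cell_types) - {r.cell_id for r in recs})
    if nodeless:
        raise ValidationError(f"cells.csv: cells without nodes: {nodeless}")

    syn_path = directory / "synapses.csv"
    synapses: list[SynapseRecord] = []
    if syn_path.exists():
        syn_df = _read_csv(syn_path, SYNAPSE_COLUMNS)
        for col in ("x_um", "y_um", "z_um"):
            if len(syn_df):
                syn_df[col] = _as_float(syn_df, col, syn_path)
        synapses = [
            SynapseRecord(
                synapse_id=r.synapse_id,
                pre_cell_id=r.pre_cell_id,
                post_cell_id=r.post_cell_id,
                kind=r.kind,
                x=float(r.x_um),
                y=float(r.y_um),
                z=float(r.z_um),
                pre_type=r.pre_type or "unclassified",
            )
            for r in syn_df.itertuples(index=False)
        ]

    ipl: Optional[IPLBoundaries] = None
    ipl_path = directory / "ipl.json"
    if ipl_path.exists():
        raw = json.loads(ipl_path.read_text())
        ipl = IPLBoundaries(float(raw["inl_ipl_z"]), float(raw["ipl_gcl_z"]))

    return Dataset(recs, synapses, ipl)


def write_dataset(dataset: Dataset, directory: Union[str, Path]) -> list[Path]:
    """Write a dataset to the CSV schema; byte-stable under fixed column order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cells = pd.DataFrame(
        [(r.cell_id, r.cell_type) for r in dataset.reconstructions],
        columns=CELL_COLUMNS,
    )
    nodes = pd.DataFrame(
        [
            (n.cell_id, n.node_id, n.parent_id or "", repr(float(n.x)),
             repr(float(n.y)), repr(float(n.z)), repr(float(n.radius)), n.tag)
            for r in dataset.reconstructions
            for n in r.nodes
        ],
        columns=NODE_COLUMNS,
    )
    syns = pd.DataFrame(
        [
            (s.synapse_id, s.pre_cell_id, s.post_cell_id, s.kind,
             repr(float(s.x)), repr(float(s.y)), repr(float(s.z)), s.pre_type)
            for s in dataset.synapses
        ],
        columns=SYNAPSE_COLUMNS,
    )
    for name, df in (("cells.csv", cells), ("nodes.csv", nodes), ("synapses.csv", syns)):
        path = directory / name
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    if dataset.ipl_boundaries is not None:
        path = directory / "ipl.json"
        path.write_text(
            json.dumps(
                {
                    "inl_ipl_z": dataset.ipl_boundaries.inl_ipl_z,
                    "ipl_gcl_z": dataset.ipl_boundaries.ipl_gcl_z,
                },
                indent=2,
            )
            + "\n"
        )
        written.append(path)
    return written


def write_swc(reconstruction: NeuronReconstruction, path: Union[str, Path]) -> Path:
    """Export one reconstruction as standard 7-column SWC (parent -1 at roots).

    Node ids are mapped to consecutive integers in node order; type codes:
    1 soma, 2 axon, 3 dendrite.
    """
    path = Path(path)
    index = {n.node_id: i + 1 for i, n in enumerate(reconstruction.nodes)}
    lines = [f"# SWC export of cell {reconstruction.cell_id} ({reconstruction.cell_type})"]
    for n in reconstruction.nodes:
        parent = index[n.parent_id] if n.parent_id is not None else -1
        lines.append(
            f"{index[n.node_id]} {SWC_TYPE_CODES[n.tag]} {n.x:.6g} {n.y:.6g} "
            f"{n.z:.6g} {n.radius:.6g} {parent}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
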