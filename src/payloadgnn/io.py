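"""Readers and writers for the supported interchange formats.

Input: SMILES lists (`.smi`, one record per line with optional tab-separated
label columns), CSV with a `smiles` column plus one column per task (empty
cells are masked labels), and SDF for molecules carrying 3D conformers.

Output: a JSON-lines interchange format, one :class:`MolecularGraph` per
line with fields mol_id, smiles, node_features, edge_index, coords, labels,
label_mask. JSON floats round-trip float64 exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .molgraph import MolecularGraph, build_graph, graph_from_mol

__all__ = [
    "read_smiles_file",
    "read_csv",
    "read_sdf",
    "graphs_from_table",
    "write_jsonl",
    "read_jsonl",
]


def read_smiles_file(path) -> pd.DataFrame:
    """`.smi` reader: SMILES first, then optional tab-separated task labels."""
    rows = []
    n_tasks = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        labels = [float(p) if p != "" else np.nan for p in parts[1:]]
        n_tasks = max(n_tasks, len(labels))
        rows.append([parts[0], *labels])
    cols = ["smiles"] + [f"task_{k}" for k in range(n_tasks)]
    return pd.DataFrame([r + [np.nan] * (len(cols) - len(r)) for r in rows], columns=cols)


def read_csv(path, smiles_col: str = "smiles") -> pd.DataFrame:
    df = pd.read_csv(path)
    if smiles_col not in df.columns:
        raise ValueError(f"CSV is missing the {smiles_col!r} column")
    return df


def graphs_from_table(
    df: pd.DataFrame,
    smiles_col: str = "smiles",
    label_cols: list[str] | None = None,
    collapse_duplicates: bool = True,
    one_hot_elements: tuple[int, ...] | None = None,
) -> list[MolecularGraph]:
    """Build graphs from a table; NaN labels become masked entries.

    SMILES are canonicalized; duplicate structures are collapsed keeping the
    first occurrence's labels, mirroring redundancy reduction during dataset
    curation.
    """
    if label_cols is None:
        label_cols = [c for c in df.columns if c != smiles_col]
    graphs: list[MolecularGraph] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        raw = np.array(
            [row[c] for c in label_cols] if label_cols else [0.0], dtype=np.float64
        )
        mask = (~np.isnan(raw)).astype(np.float64)
        labels = np.nan_to_num(raw)
        g = build_graph(
            row[smiles_col],
            labels=labels,
            label_mask=mask,
            one_hot_elements=one_hot_elements,
        )
        if collapse_duplicates:
            if g.smiles in seen:
                continue
            seen.add(g.smiles)
        graphs.append(g)
    return graphs


def read_sdf(
    path,
    label_property: str | None = None,
    one_hot_elements: tuple[int, ...] | None = None,
) -> list[MolecularGraph]:
    """SDF reader; records with 3D coordinates yield graphs with coords.

    Unparseable records are skipped with a warning rather than aborting the
    whole file. Multiple records of the same structure are kept as separate
    graphs sharing a mol_id (one per conformer/pose).
    """
    graphs: list[MolecularGraph] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for k, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"skipping unreadable SDF record {k}")
            continue
        label = (
            float(mol.GetProp(label_property))
            if label_property and mol.HasProp(label_property)
            else np.nan
        )
        coords = (
            np.asarray(mol.GetConformer().GetPositions(), dtype=np.float64)
            if mol.GetNumConformers()
            else None
        )
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else Chem.MolToSmiles(mol)
        graphs.append(
            graph_from_mol(
                mol,
                coords=coords,
                labels=[0.0 if np.isnan(label) else label],
                label_mask=[0.0 if np.isnan(label) else 1.0],
                mol_id=name,
                one_hot_elements=one_hot_elements,
            )
        )
    return graphs


# ------------------------------------------------------------------- JSONL
def write_jsonl(graphs: list[MolecularGraph], path) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(
                json.dumps(
                    {
                        "mol_id": g.mol_id,
                        "smiles": g.smiles,
                        "node_features": g.node_features.tolist(),
                        "edge_index": np.asarray(g.edge_index).tolist(),
                        "coords": None if g.coords is None else g.coords.tolist(),
                        "labels": g.labels.tolist(),
                        "label_mask": g.label_mask.tolist(),
                    }
                )
                + "\n"
            )


def read_jsonl(path) -> list[MolecularGraph]:
    graphs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        n = len(d["node_features"])
        graphs.append(
            MolecularGraph(
                node_features=np.asarray(d["node_features"], dtype=np.float64).reshape(n, -1),
                edge_index=np.asarray(d["edge_index"], dtype=np.int64).reshape(-1, 2),
                coords=None
                if d["coords"] is None
                else np.asarray(d["coords"], dtype=np.float64),
                labels=np.asarray(d["labels"], dtype=np.float64),
                label_mask=np.asarray(d["label_mask"], dtype=np.float64),
                mol_id=d["mol_id"],
                smiles=d["smiles"],
            )
        )
    return graphs
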