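"""Attention collection and the quantitative interpretability framework.

Every GAT layer's softmax-normalized attention weights are collected per
(molecule, layer, head, edge) and summarized layer-wise: Shannon entropy of
the pooled weight distribution (natural log), raw-weight mean/std, each
head's share of total attention mass, and the effective number of heads —
the perplexity exp(H) of the head-importance distribution, bounded by
[1, n_heads] with the extremes attained exactly at one-hot and uniform
importance. "Diversity" is reported as the variance of head importance.

Atom-level attribution uses the mean incoming attention weight at the final
GAT layer (heads averaged, self-edges included) and aggregates it over
matched substructures: SMARTS patterns, Bemis–Murcko scaffolds, BRICS
fragments, and fixed-size rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import BRICS
from scipy import stats

from .errors import CapabilityError, SmilesParseError
from .model import HybridGNN
from .molgraph import MolecularGraph
from .training import make_batches, murcko_scaffold

__all__ = [
    "AttentionRecord",
    "LayerAttentionStats",
    "AttentionSummary",
    "SubstructureAttribution",
    "collect_attention",
    "records_frame",
    "summarize_attention",
    "atom_attention_scores",
    "attribute_smarts",
    "attribute_murcko",
    "attribute_brics",
    "ring_system_attribution",
    "motif_discrimination_test",
]


@dataclass(frozen=True)
class AttentionRecord:
    """One attention weight: α for (molecule, layer, head, edge i→j)."""

    mol_id: str
    layer_index: int
    head_index: int
    edge: tuple[int, int]  # (attending node i, attended node j), self-edges included
    weight: float


@dataclass
class LayerAttentionStats:
    layer_index: int
    entropy: float  # nats, of the pooled renormalized weight distribution
    std: float  # of the raw pooled weights
    mean: float
    effective_heads: float
    head_importance: np.ndarray
    diversity: float  # variance of head_importance


@dataclass
class AttentionSummary:
    layers: list[LayerAttentionStats]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer": [s.layer_index for s in self.layers],
                "entropy": [s.entropy for s in self.layers],
                "std": [s.std for s in self.layers],
                "mean": [s.mean for s in self.layers],
                "effective_heads": [s.effective_heads for s in self.layers],
                "diversity": [s.diversity for s in self.layers],
            }
        )


@dataclass
class SubstructureAttribution:
    """Aggregated attention over one substructure pattern."""

    kind: str  # smarts | murcko_scaffold | brics_fragment | ring_system
    pattern: str
    matches: dict[str, list[tuple[int, ...]]] = field(default_factory=dict)
    mean_attention: float = float("nan")
    std_attention: float = float("nan")
    n_molecules_matched: int = 0


# ----------------------------------------------------------------- collection
def collect_attention(
    model: HybridGNN, graphs: list[MolecularGraph], node_budget: int = 2000
) -> list[AttentionRecord]:
    """Run the model and emit every attention weight as a record.

    Node indices are mapped back to within-molecule numbering. Raises
    :class:`CapabilityError` for variants without attention layers.
    """
    if not any(kind == "gat" for _, kind, *_ in model.plan):
        raise CapabilityError(
            f"variant {model.config.variant!r} has no attention layers"
        )
    records: list[AttentionRecord] = []
    for batch in make_batches(graphs, node_budget, model.config.wants_coords):
        _, attention = model.forward(batch, collect_attention=True)
        offsets = np.zeros(batch.n_graphs, dtype=np.int64)
        counts = np.bincount(batch.graph_id, minlength=batch.n_graphs)
        offsets[1:] = np.cumsum(counts)[:-1]
        for layer_idx, alpha, edges_sl in attention:
            gid = batch.graph_id[edges_sl[:, 0]]
            local = edges_sl - offsets[gid][:, None]
            for e in range(edges_sl.shape[0]):
                mol = batch.mol_ids[gid[e]]
                i, j = int(local[e, 0]), int(local[e, 1])
                for h in range(alpha.shape[1]):
                    records.append(
                        AttentionRecord(mol, layer_idx, h, (i, j), float(alpha[e, h]))
                    )
    return records


def records_frame(records: list[AttentionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mol_id": [r.mol_id for r in records],
            "layer": np.fromiter((r.layer_index for r in records), dtype=np.int64, count=len(records)),
            "head": np.fromiter((r.head_index for r in records), dtype=np.int64, count=len(records)),
            "src": np.fromiter((r.edge[0] for r in records), dtype=np.int64, count=len(records)),
            "dst": np.fromiter((r.edge[1] for r in records), dtype=np.int64, count=len(records)),
            "weight": np.fromiter((r.weight for r in records), dtype=np.float64, count=len(records)),
        }
    )


# ------------------------------------------------------------------ summaries
def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def summarize_attention(records: list[AttentionRecord]) -> AttentionSummary:
    """Layer-wise entropy/std/mean, head importance and effective heads.

    The entropy is computed on the layer's weights pooled over molecules,
    heads and edges, renormalized to a probability distribution; mean and
    std are computed on the raw pooled weights.

    Head importance is each head's share of *neighbor-directed* attention
    mass (self-edges excluded). Because every head's softmax sums to one per
    node, the share of total mass is identically uniform and carries no
    signal; the neighbor-directed share measures how strongly a head looks
    beyond the focal atom and differs between heads. When a layer has only
    self-edges (single-atom graphs) the total mass is used as a fallback.
    """
    if not records:
        raise ValueError("no attention records to summarize")
    df = records_frame(records)
    n_heads = int(df["head"].max()) + 1
    layers = []
    for layer, sub in df.groupby("layer"):
        w = sub["weight"].to_numpy()
        pooled = w / w.sum()
        nonself = sub[sub["src"] != sub["dst"]]
        basis = nonself if len(nonself) and nonself["weight"].sum() > 0 else sub
        head_mass = np.zeros(n_heads)
        grouped = basis.groupby("head")["weight"].sum()
        head_mass[grouped.index.to_numpy()] = grouped.to_numpy()
        importance = head_mass / head_mass.sum()
        layers.append(
            LayerAttentionStats(
                layer_index=int(layer),
                entropy=_shannon(pooled),
                std=float(w.std()),
                mean=float(w.mean()),
                effective_heads=float(np.exp(_shannon(importance))),
                head_importance=importance,
                diversity=float(importance.var()),
            )
        )
    return AttentionSummary(layers=sorted(layers, key=lambda s: s.layer_index))


def atom_attention_scores(
    records: list[AttentionRecord], layer: int | None = None
) -> dict[str, dict[int, float]]:
    """Per-atom score: mean incoming attention weight, heads averaged.

    Defaults to the final attention layer. Self-edges carry mass and are
    included. Returns mol_id → {atom index → score}.
    """
    df = records_frame(records)
    target_layer = int(df["layer"].max()) if layer is None else layer
    df = df[df["layer"] == target_layer]
    out: dict[str, dict[int, float]] = {}
    for (mol, dst), grp in df.groupby(["mol_id", "dst"]):
        out.setdefault(mol, {})[int(dst)] = float(grp["weight"].mean())
    return out


# ---------------------------------------------------------------- attribution
def _unique_mols(graphs: list[MolecularGraph]) -> dict[str, Chem.Mol]:
    mols: dict[str, Chem.Mol] = {}
    for g in graphs:
        if g.mol_id not in mols:
            mol = Chem.MolFromSmiles(g.smiles)
            if mol is None:
                raise SmilesParseError(g.smiles)
            mols[g.mol_id] = mol
    return mols


def _aggregate(
    kind: str,
    pattern: str,
    matches: dict[str, list[tuple[int, ...]]],
    scores: dict[str, dict[int, float]],
) -> SubstructureAttribution:
    values = []
    n_matched = 0
    for mol_id, match_list in matches.items():
        atom_set = sorted({a for m in match_list for a in m})
        if not atom_set:
            continue
        n_matched += 1
        mol_scores = scores.get(mol_id, {})
        values.extend(mol_scores[a] for a in atom_set if a in mol_scores)
    arr = np.asarray(values, dtype=np.float64)
    return SubstructureAttribution(
        kind=kind,
        pattern=pattern,
        matches=matches,
        mean_attention=float(arr.mean()) if arr.size else float("nan"),
        std_attention=float(arr.std()) if arr.size else float("nan"),
        n_molecules_matched=n_matched,
    )


def attribute_smarts(
    graphs: list[MolecularGraph],
    records: list[AttentionRecord],
    smarts_patterns: list[str],
) -> list[SubstructureAttribution]:
    """Attention attribution for SMARTS-defined functional groups."""
    scores = atom_attention_scores(records)
    mols = _unique_mols(graphs)
    out = []
    for pattern in smarts_patterns:
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise SmilesParseError(pattern, kind="SMARTS")
        matches = {
            mol_id: [tuple(m) for m in mol.GetSubstructMatches(query)]
            for mol_id, mol in mols.items()
        }
        out.append(_aggregate("smarts", pattern, matches, scores))
    return out


def attribute_murcko(
    graphs: list[MolecularGraph], records: list[AttentionRecord]
) -> list[SubstructureAttribution]:
    """Attribution over Bemis–Murcko scaffold atoms, one entry per scaffold.

    Acyclic molecules have the empty scaffold; they are grouped under the
    empty pattern with no matched atoms.
    """
    scores = atom_attention_scores(records)
    mols = _unique_mols(graphs)
    by_scaffold: dict[str, dict[str, list[tuple[int, ...]]]] = {}
    for mol_id, mol in mols.items():
        scaffold = murcko_scaffold(Chem.MolToSmiles(mol))
        matches: list[tuple[int, ...]] = []
        if scaffold:
            query = Chem.MolFromSmiles(scaffold)
            hit = mol.GetSubstructMatch(query)
            if hit:
                matches = [tuple(hit)]
        by_scaffold.setdefault(scaffold, {})[mol_id] = matches
    out = []
    for scaffold, matches in sorted(by_scaffold.items()):
        attribution = _aggregate("murcko_scaffold", scaffold, matches, scores)
        if scaffold == "":
            attribution.n_molecules_matched = len(matches)  # present, atom set empty
        out.append(attribution)
    return out


def _brics_fragments(mol: Chem.Mol) -> list[tuple[tuple[int, ...], str]]:
    """Atom-index sets of the BRICS fragments, keyed by fragment SMILES."""
    n = mol.GetNumAtoms()
    bonds = [
        mol.GetBondBetweenAtoms(i, j).GetIdx()
        for (i, j), _ in BRICS.FindBRICSBonds(mol)
    ]
    if not bonds:
        return [(tuple(range(n)), Chem.MolToSmiles(mol))]
    broken = Chem.FragmentOnBonds(mol, bonds, addDummies=False)
    frags = Chem.GetMolFrags(broken)
    out = []
    for frag in frags:
        atoms = tuple(a for a in frag if a < n)
        out.append((atoms, Chem.MolFragmentToSmiles(mol, atomsToUse=list(atoms))))
    return out


def attribute_brics(
    graphs: list[MolecularGraph], records: list[AttentionRecord]
) -> list[SubstructureAttribution]:
    """Attribution over BRICS retrosynthetic fragments, keyed by the
    canonical fragment string; a molecule with no BRICS bonds is one
    fragment, itself."""
    scores = atom_attention_scores(records)
    mols = _unique_mols(graphs)
    by_fragment: dict[str, dict[str, list[tuple[int, ...]]]] = {}
    for mol_id, mol in mols.items():
        for atoms, key in _brics_fragments(mol):
            by_fragment.setdefault(key, {}).setdefault(mol_id, []).append(atoms)
    return [
        _aggregate("brics_fragment", key, matches, scores)
        for key, matches in sorted(by_fragment.items())
    ]


def ring_system_attribution(
    graphs: list[MolecularGraph],
    records: list[AttentionRecord],
    ring_size: int = 5,
) -> SubstructureAttribution:
    """Attribution over all SSSR rings of exactly `ring_size` atoms."""
    if ring_size < 3:
        raise ValueError("ring_size must be ≥ 3")
    scores = atom_attention_scores(records)
    mols = _unique_mols(graphs)
    matches: dict[str, list[tuple[int, ...]]] = {}
    for mol_id, mol in mols.items():
        rings = [
            tuple(r)
            for r in mol.GetRingInfo().AtomRings()
            if len(r) == ring_size
        ]
        if rings:
            matches[mol_id] = rings
    return _aggregate("ring_system", f"{ring_size}-membered ring", matches, scores)


# ----------------------------------------------------------------- statistics
def motif_discrimination_test(
    graphs: list[MolecularGraph],
    records: list[AttentionRecord],
    motif_smarts: str,
) -> tuple[np.ndarray, float]:
    """Paired one-sided test: motif atoms vs background atoms.

    For every molecule containing the motif and at least one background
    atom, computes (mean motif-atom score − mean background score); returns
    the paired differences and the one-sided Wilcoxon signed-rank p-value
    for the alternative that motif attention is greater.
    """
    query = Chem.MolFromSmarts(motif_smarts)
    if query is None:
        raise SmilesParseError(motif_smarts, kind="SMARTS")
    scores = atom_attention_scores(records)
    mols = _unique_mols(graphs)
    diffs = []
    for mol_id, mol in mols.items():
        hits = mol.GetSubstructMatches(query)
        if not hits or mol_id not in scores:
            continue
        motif_atoms = {a for m in hits for a in m}
        background = set(range(mol.GetNumAtoms())) - motif_atoms
        if not background:
            continue
        s = scores[mol_id]
        diffs.append(
            np.mean([s[a] for a in motif_atoms]) - np.mean([s[a] for a in background])
        )
    diffs = np.asarray(diffs)
    if diffs.size == 0:
        raise ValueError("no molecule contains the motif")
    _, p = stats.wilcoxon(diffs, alternative="greater")
    return diffs, float(p)
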