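"""Self-contained synthetic inputs: planted-motif molecule sets, abstract
random graphs, and 3D conformer embedding.

The planted-motif task is the package's stand-in for a curated bioactivity
set: positives carry a grafted functional-group motif (default: the ester
pattern COC(=O), a recurring pharmacophoric element of Topoisomerase I
inhibitor payloads), negatives are built from the same backbone/decoration
pool with zero motif matches, so the label is exactly motif presence (up to
optional label noise). Backbones span distinct ring systems so Murcko
scaffold splitting produces non-degenerate partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import SmilesParseError
from .molgraph import ConformerSet, MolecularGraph, build_graph

__all__ = [
    "MotifTaskSpec",
    "DEFAULT_SCAFFOLD_POOL",
    "DEFAULT_DECORATIONS",
    "generate_motif_task",
    "generate_random_graphs",
    "embed_coords",
    "attach_coords",
    "motif_task_graphs",
]

#: ring-diverse backbones (plus a few alkyl chains) so scaffold splits have
#: many groups to distribute
DEFAULT_SCAFFOLD_POOL = (
    "c1ccccc1",  # benzene
    "c1ccncc1",  # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "c1ccoc1",  # furan
    "c1ccsc1",  # thiophene
    "c1cscn1",  # thiazole
    "C1CCSC1",  # tetrahydrothiophene
    "c1cc[nH]c1",  # pyrrole
    "C1CCCCC1",  # cyclohexane
    "C1CCCC1",  # cyclopentane
    "C1CCOC1",  # tetrahydrofuran
    "C1CCNCC1",  # piperidine
    "C1CCOCC1",  # tetrahydropyran
    "c1cnc2ccccc2c1",  # quinoline
    "CCCCC",
    "CCCCCC",
    "CC(C)CC",
)

#: motif-free decorations shared by both classes
DEFAULT_DECORATIONS = ("C", "O", "N", "F", "CC", "C#N", "C(=O)N", "C(C)C")

#: the grafted ester: attached through atom 0 (the carbonyl carbon) it
#: yields R–C(=O)–O–CH3, matching the SMARTS COC(=O)
_MOTIF_FRAGMENT = ("C(=O)OC", 0)


@dataclass
class MotifTaskSpec:
    """Conditions of one planted-motif classification task."""

    motif_smarts: str = "COC(=O)"
    n_molecules: int = 600
    positive_fraction: float = 0.5
    scaffold_pool: tuple[str, ...] = DEFAULT_SCAFFOLD_POOL
    seed: int = 0
    label_noise: float = 0.0
    max_decorations: int = 2

    def __post_init__(self):
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not self.scaffold_pool:
            raise ValueError("scaffold pool is empty")


def _attach(mol: Chem.Mol, frag_smiles: str, attach_idx: int, rng) -> Chem.Mol | None:
    """Graft a fragment onto a random H-bearing atom; None on failure."""
    frag = Chem.MolFromSmiles(frag_smiles)
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
    if not sites:
        return None
    site = int(rng.choice(sites))
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    combined.AddBond(site, mol.GetNumAtoms() + attach_idx, Chem.BondType.SINGLE)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _build_molecule(spec: MotifTaskSpec, positive: bool, query: Chem.Mol, rng) -> str | None:
    mol = Chem.MolFromSmiles(str(rng.choice(spec.scaffold_pool)))
    for _ in range(int(rng.integers(0, spec.max_decorations + 1))):
        decorated = _attach(mol, str(rng.choice(DEFAULT_DECORATIONS)), 0, rng)
        if decorated is not None:
            mol = decorated
    if positive:
        frag, attach_idx = _MOTIF_FRAGMENT
        mol = _attach(mol, frag, attach_idx, rng)
        if mol is None:
            return None
    n_hits = len(mol.GetSubstructMatches(query))
    if (positive and n_hits == 0) or (not positive and n_hits > 0):
        return None
    return Chem.MolToSmiles(mol)


def generate_motif_task(spec: MotifTaskSpec) -> pd.DataFrame:
    """Labeled molecule table (mol_id, smiles, label, has_motif).

    Exactly round(n · positive_fraction) structures carry the motif;
    `label` equals motif presence XOR seeded noise flips. Emitted SMILES are
    canonical, chemically valid and pairwise distinct.
    """
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")  # rejected graft attempts are expected
    try:
        return _generate_motif_task(spec)
    finally:
        RDLogger.EnableLog("rdApp.error")


def _generate_motif_task(spec: MotifTaskSpec) -> pd.DataFrame:
    rng = np.random.default_rng(spec.seed)
    # separate stream so the molecule set is identical across noise levels
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    query = Chem.MolFromSmarts(spec.motif_smarts)
    if query is None:
        raise SmilesParseError(spec.motif_smarts, kind="SMARTS")
    n_pos = int(round(spec.n_molecules * spec.positive_fraction))
    flags = [True] * n_pos + [False] * (spec.n_molecules - n_pos)
    rng.shuffle(flags)
    seen: set[str] = set()
    rows = []
    for i, positive in enumerate(flags):
        smiles = None
        for _ in range(200):  # bounded resampling on graft failure/duplicates
            smiles = _build_molecule(spec, positive, query, rng)
            if smiles is not None and smiles not in seen:
                break
            smiles = None
        if smiles is None:
            raise RuntimeError(
                "could not construct a fresh "
                f"{'positive' if positive else 'negative'} molecule"
            )
        seen.add(smiles)
        label = int(positive)
        if noise_rng.random() < spec.label_noise:
            label = 1 - label
        rows.append(
            {
                "mol_id": f"mol{i:05d}",
                "smiles": smiles,
                "label": label,
                "has_motif": int(positive),
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- random graphs
def generate_random_graphs(
    n_graphs: int,
    node_range: tuple[int, int] = (2, 10),
    feature_dim: int = 5,
    seed: int = 0,
    with_coords: bool = False,
    extra_edge_prob: float = 0.3,
) -> list[MolecularGraph]:
    """Connected abstract graphs with random features, for layer-level tests.

    A random spanning tree guarantees connectivity; extra undirected edges
    are sprinkled on top. Both directions of every edge are stored, and
    optional coordinates are centroid-centered.
    """
    rng = np.random.default_rng(seed)
    lo, hi = node_range
    if lo < 1:
        raise ValueError("node_range minimum must be ≥ 1")
    graphs = []
    for k in range(n_graphs):
        n = int(rng.integers(lo, hi + 1))
        pairs: set[tuple[int, int]] = set()
        for v in range(1, n):
            u = int(rng.integers(0, v))
            pairs.add((u, v))
        for u in range(n):
            for v in range(u + 1, n):
                if (u, v) not in pairs and rng.random() < extra_edge_prob / max(n - 1, 1):
                    pairs.add((u, v))
        edges = []
        for u, v in sorted(pairs):
            edges.extend([(u, v), (v, u)])
        coords = None
        if with_coords:
            coords = rng.normal(size=(n, 3))
            coords -= coords.mean(axis=0)
        g = MolecularGraph(
            node_features=rng.normal(size=(n, feature_dim)),
            edge_index=np.asarray(edges, dtype=np.int64)
            if edges
            else np.zeros((0, 2), dtype=np.int64),
            labels=np.array([float(rng.integers(0, 2))]),
            label_mask=np.ones(1),
            mol_id=f"graph{k:04d}",
            smiles="",
            coords=coords,
        )
        g.validate()
        graphs.append(g)
    return graphs


# ------------------------------------------------------------------ conformers
def _principal_axis_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate centered coordinates into a canonical principal-axis frame.

    Embedding engines return an arbitrary orientation, which would feed the
    model pure per-molecule noise; real pose data (e.g. docked conformers)
    share a binding-pocket frame instead. Aligning each conformer to its
    principal axes — signs fixed by the coordinate-skewness rule, third
    axis by right-handedness — removes the arbitrary rotation
    deterministically while preserving internal geometry and chirality.
    """
    if coords.shape[0] < 2:
        return coords
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    axes = np.eye(3)
    axes[:, : vt.shape[0]] = vt.T
    for k in range(2):
        if np.sum((coords @ axes[:, k]) ** 3) < 0:
            axes[:, k] = -axes[:, k]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return coords @ axes


def embed_coords(
    smiles_list: list[str], seed: int = 0, n_conformers: int = 1, optimize: bool = True
) -> tuple[list[ConformerSet], list[tuple[str, str]]]:
    """ETKDG conformer embedding with MMFF94 minimization.

    Returns (conformer sets, failures); a failure is (smiles, reason) and
    the molecule is simply absent from the conformer sets — callers decide
    whether to exclude it from 3D variants. Heavy-atom coordinates are
    centroid-centered, rotated into a canonical principal-axis frame, and
    ordered like the canonical heavy-atom graph.
    """
    sets: list[ConformerSet] = []
    failures: list[tuple[str, str]] = []
    for i, smiles in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            failures.append((smiles, "unparseable SMILES"))
            continue
        canonical = Chem.MolToSmiles(mol)
        mol = Chem.AddHs(Chem.MolFromSmiles(canonical))
        params = AllChem.ETKDGv3()
        params.randomSeed = int((seed * 100003 + i) % (2**31 - 1))
        conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
        if not conf_ids:
            failures.append((canonical, "embedding failed"))
            continue
        conformers = []
        for cid in conf_ids:
            energy = None
            if optimize:
                try:
                    AllChem.MMFFOptimizeMolecule(mol, confId=cid)
                    props = AllChem.MMFFGetMoleculeProperties(mol)
                    if props is not None:
                        ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
                        energy = float(ff.CalcEnergy())
                except Exception:
                    pass
            heavy = Chem.RemoveHs(mol)
            coords = np.asarray(
                heavy.GetConformer(cid).GetPositions(), dtype=np.float64
            )
            conformers.append(
                (_principal_axis_frame(coords - coords.mean(axis=0)), energy)
            )
        sets.append(ConformerSet(mol_id=canonical, conformers=conformers))
    return sets, failures


def attach_coords(
    graphs: list[MolecularGraph], conformer_sets: list[ConformerSet]
) -> list[MolecularGraph]:
    """One graph per (molecule, conformer), sharing the molecule's mol_id.

    Molecules without conformers are dropped (they cannot feed 3D variants);
    callers receive exactly the records that have geometry.
    """
    by_smiles = {c.mol_id: c for c in conformer_sets}
    out = []
    for g in graphs:
        conf = by_smiles.get(g.smiles)
        if conf is None:
            continue
        for coords, _ in conf.conformers:
            out.append(g.with_coords(coords))
    return out


def motif_task_graphs(
    spec: MotifTaskSpec, embed_3d: bool = True
) -> tuple[list[MolecularGraph], pd.DataFrame]:
    """Convenience: generate the task and build (optionally 3D) graphs."""
    df = generate_motif_task(spec)
    graphs = [
        build_graph(row.smiles, labels=[float(row.label)], mol_id=row.mol_id)
        for row in df.itertuples()
    ]
    if embed_3d:
        sets, failures = embed_coords(df["smiles"].tolist(), seed=spec.seed)
        if failures:
            import warnings

            warnings.warn(f"{len(failures)} molecule(s) failed 3D embedding")
        graphs = attach_coords(graphs, sets)
    return graphs, df
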