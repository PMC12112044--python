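"""Molecules as attributed graphs.

Converts SMILES strings (optionally with supplied 3D conformer coordinates)
into heavy-atom graphs carrying the six-descriptor atomic featurization used
throughout the package: atomic number, heavy-atom degree, attached hydrogen
count, implicit valence, aromaticity flag, and (optionally) centered 3D
coordinates. Also houses the dataset-preparation rules: IC50 binarization at
a 100 µM cutoff and greedy RMSD-based conformer deduplication.

Hydrogens are implicit: they appear only through the hydrogen-count feature,
never as graph nodes. Every bond contributes two directed edge entries so the
edge list is symmetric.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .errors import ShapeError, SmilesParseError

__all__ = [
    "AtomFeatureVector",
    "MolecularGraph",
    "ConformerSet",
    "N_BASE_FEATURES",
    "mol_from_smiles",
    "featurize_atom",
    "featurize_mol",
    "build_graph",
    "label_from_ic50",
    "kabsch_rmsd",
    "prune_conformers",
]

#: length of the 2D feature vector (atomic number, degree, H count,
#: implicit valence, aromatic flag)
N_BASE_FEATURES = 5


@dataclass(frozen=True)
class AtomFeatureVector:
    """Per-atom chemical descriptors; coords in Å when present."""

    atomic_number: int
    degree: int
    num_hydrogens: int
    implicit_valence: int
    is_aromatic: int
    coords: np.ndarray | None = None

    def as_array(self) -> np.ndarray:
        base = np.array(
            [
                self.atomic_number,
                self.degree,
                self.num_hydrogens,
                self.implicit_valence,
                self.is_aromatic,
            ],
            dtype=np.float64,
        )
        if self.coords is None:
            return base
        return np.concatenate([base, np.asarray(self.coords, dtype=np.float64)])


@dataclass
class MolecularGraph:
    """A heavy-atom molecular graph plus labels; the unit every layer consumes.

    `edge_index` holds ordered pairs (i, j): node i has j in its neighborhood.
    Both directions of every bond are present. `coords`, when given, are
    centered on the molecular centroid.
    """

    node_features: np.ndarray
    edge_index: np.ndarray  # (E, 2) int array, possibly E == 0
    labels: np.ndarray
    label_mask: np.ndarray
    mol_id: str
    smiles: str
    coords: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[0]

    def validate(self) -> None:
        n = self.n_atoms
        e = np.asarray(self.edge_index)
        if e.size:
            if e.min() < 0 or e.max() >= n:
                raise ShapeError(f"edge index out of range for {n} atoms")
            if np.any(e[:, 0] == e[:, 1]):
                raise ShapeError("self-loops are not stored in molecular graphs")
            pairs = {(int(i), int(j)) for i, j in e}
            if any((j, i) not in pairs for i, j in pairs):
                raise ShapeError("edge list is not symmetric")
        if self.coords is not None:
            if self.coords.shape != (n, 3):
                raise ShapeError(
                    f"coords shape {self.coords.shape} != ({n}, 3)"
                )
            if n and np.abs(self.coords.mean(axis=0)).max() > 1e-6:
                raise ShapeError("coords are not centroid-centered")
        if self.labels.shape != self.label_mask.shape:
            raise ShapeError("labels and label_mask shapes differ")

    def with_coords(self, coords: np.ndarray) -> "MolecularGraph":
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (self.n_atoms, 3):
            raise ShapeError(
                f"coords shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        return dataclasses.replace(self, coords=coords - coords.mean(axis=0))


@dataclass
class ConformerSet:
    """3D conformers of one molecule; energies in kcal/mol when known."""

    mol_id: str
    conformers: list[tuple[np.ndarray, float | None]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.conformers)


# --------------------------------------------------------------------- atoms
def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and canonicalize; atom order follows the canonical SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    return mol


def featurize_atom(mol: Chem.Mol, atom_index: int) -> AtomFeatureVector:
    """The six-descriptor feature vector of one atom (coords left unset)."""
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise IndexError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    return AtomFeatureVector(
        atomic_number=atom.GetAtomicNum(),
        degree=atom.GetDegree(),
        num_hydrogens=atom.GetTotalNumHs(),
        implicit_valence=atom.GetImplicitValence(),
        is_aromatic=int(atom.GetIsAromatic()),
    )


def featurize_mol(
    mol: Chem.Mol, one_hot_elements: tuple[int, ...] | None = None
) -> np.ndarray:
    """Stack per-atom feature vectors into the node-feature matrix.

    With `one_hot_elements`, the atomic-number column is replaced by a
    one-hot block over that fixed element vocabulary (unknown elements map
    to an all-zero block).
    """
    rows = [featurize_atom(mol, i).as_array() for i in range(mol.GetNumAtoms())]
    x = np.asarray(rows, dtype=np.float64).reshape(mol.GetNumAtoms(), N_BASE_FEATURES)
    if one_hot_elements is None:
        return x
    vocab = {z: k for k, z in enumerate(one_hot_elements)}
    onehot = np.zeros((x.shape[0], len(one_hot_elements)))
    for i, z in enumerate(x[:, 0].astype(int)):
        if z in vocab:
            onehot[i, vocab[z]] = 1.0
    return np.concatenate([onehot, x[:, 1:]], axis=1)


def graph_from_mol(
    mol: Chem.Mol,
    coords: np.ndarray | None = None,
    labels=(0.0,),
    label_mask=None,
    mol_id: str | None = None,
    one_hot_elements: tuple[int, ...] | None = None,
) -> MolecularGraph:
    """Build a graph from an RDKit Mol in its *native* atom order.

    Used when coordinates are tied to an existing atom numbering (e.g. SDF
    conformers); `build_graph` is the canonical-order entry point for SMILES.
    """
    x = featurize_mol(mol, one_hot_elements=one_hot_elements)
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.extend([(i, j), (j, i)])
    edge_index = (
        np.asarray(edges, dtype=np.int64) if edges else np.zeros((0, 2), dtype=np.int64)
    )
    labels = np.atleast_1d(np.asarray(labels, dtype=np.float64))
    if label_mask is None:
        label_mask = np.ones_like(labels)
    label_mask = np.atleast_1d(np.asarray(label_mask, dtype=np.float64))
    if coords is not None:
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (mol.GetNumAtoms(), 3):
            raise ShapeError(
                f"coords shape {coords.shape} does not match "
                f"{mol.GetNumAtoms()} heavy atoms"
            )
        coords = coords - coords.mean(axis=0)
    smiles = Chem.MolToSmiles(mol)
    graph = MolecularGraph(
        node_features=x,
        edge_index=edge_index,
        labels=labels,
        label_mask=label_mask,
        mol_id=mol_id if mol_id is not None else smiles,
        smiles=smiles,
        coords=coords,
    )
    graph.validate()
    return graph


def build_graph(
    smiles: str,
    coords: np.ndarray | None = None,
    labels=(0.0,),
    label_mask=None,
    mol_id: str | None = None,
    one_hot_elements: tuple[int, ...] | None = None,
) -> MolecularGraph:
    """SMILES (plus optional conformer coordinates) → MolecularGraph.

    Coordinates must be indexed by the canonical heavy-atom order; they are
    re-centered on the centroid before storage. Orientation is untouched.
    """
    mol = mol_from_smiles(smiles)
    return graph_from_mol(
        mol,
        coords=coords,
        labels=labels,
        label_mask=label_mask,
        mol_id=mol_id,
        one_hot_elements=one_hot_elements,
    )


# -------------------------------------------------------------- data prep
def label_from_ic50(ic50_uM: float, cutoff_uM: float = 100.0) -> int:
    """Binarize an IC50: strictly below the cutoff is active (1)."""
    if not ic50_uM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_uM}")
    return int(ic50_uM < cutoff_uM)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations under optimal superposition.

    Both coordinate sets are centered, then the optimal proper rotation is
    found by SVD of the cross-covariance (Kabsch); no reflection is allowed.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ShapeError(f"conformer shapes differ: {a.shape} vs {b.shape}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = a @ rot - b
    return float(np.sqrt((diff**2).sum() / a.shape[0]))


def prune_conformers(conf_set: ConformerSet, rmsd_cutoff_A: float = 1.5) -> ConformerSet:
    """Greedy deduplication: keep a conformer iff it sits further than the
    RMSD cutoff from every conformer already kept, scanning in input order."""
    if len(conf_set) == 0:
        raise ValueError(f"conformer set {conf_set.mol_id!r} is empty")
    kept: list[tuple[np.ndarray, float | None]] = []
    for coords, energy in conf_set.conformers:
        if all(kabsch_rmsd(coords, k) > rmsd_cutoff_A for k, _ in kept):
            kept.append((coords, energy))
    return ConformerSet(mol_id=conf_set.mol_id, conformers=kept)
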