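"""Splitting, optimization, early stopping and the eight-metric evaluation.

The protocol: scaffold (Bemis–Murcko) or random 8:1:1 splits at the molecule
level, AdamW with decoupled weight decay at an initial learning rate of 1e-4,
up to 1000 epochs with early stopping at patience 50 on validation ROC-AUC,
and dynamic batch sizing realized as a node-count budget per batch. Multiple
3D records (conformers/poses) of one molecule always share a partition, and
at evaluation a molecule's score is the mean over its records — splitting by
record would leak near-identical structures across partitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.metrics import average_precision_score, roc_auc_score

from .autodiff import Tensor, bce_with_logits
from .errors import ConfigError, NumericError
from .model import GraphBatch, HybridGNN, batch_graphs
from .molgraph import MolecularGraph

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "MetricsReport",
    "murcko_scaffold",
    "scaffold_split",
    "random_split",
    "make_batches",
    "masked_loss",
    "AdamW",
    "EarlyStopper",
    "train",
    "compute_metrics",
    "aggregate_by_molecule",
    "evaluate",
]

PARTITIONS = ("train", "valid", "test")


# ------------------------------------------------------------------ splitting
@dataclass
class SplitSpec:
    strategy: str
    fractions: tuple[float, float, float]
    seed: int
    assignment: dict[str, str]  # mol_id → partition

    def partitions(
        self, graphs: list[MolecularGraph]
    ) -> dict[str, list[MolecularGraph]]:
        out: dict[str, list[MolecularGraph]] = {p: [] for p in PARTITIONS}
        for g in graphs:
            out[self.assignment[g.mol_id]].append(g)
        return out

    def sizes(self) -> dict[str, int]:
        out = {p: 0 for p in PARTITIONS}
        for p in self.assignment.values():
            out[p] += 1
        return out


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko scaffold SMILES; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def _molecule_table(graphs: list[MolecularGraph]) -> dict[str, str]:
    """mol_id → SMILES for the distinct molecules (first record wins)."""
    mols: dict[str, str] = {}
    for g in graphs:
        mols.setdefault(g.mol_id, g.smiles)
    return mols


def _check_fractions(fractions) -> tuple[float, float, float]:
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ConfigError(f"fractions must be 3 non-negatives summing to 1: {fractions}")
    return fractions


def scaffold_split(
    graphs: list[MolecularGraph],
    fractions=(0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitSpec:
    """Murcko-scaffold split: no scaffold ever straddles two partitions.

    Scaffold groups are sorted by (size descending, scaffold string
    ascending) and assigned greedily to the partition with the largest
    remaining deficit relative to its target fraction (ties resolved
    train → valid → test). Deterministic for fixed input; `seed` is kept for
    interface parity with the random strategy.
    """
    if not graphs:
        raise ValueError("cannot split an empty dataset")
    fractions = _check_fractions(fractions)
    mols = _molecule_table(graphs)
    groups: dict[str, list[str]] = {}
    for mol_id, smi in mols.items():
        groups.setdefault(murcko_scaffold(smi), []).append(mol_id)
    if len(groups) < len(PARTITIONS):
        warnings.warn(
            f"only {len(groups)} scaffold group(s) for {len(PARTITIONS)} partitions;"
            " some partitions will be empty"
        )
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(mols)
    targets = {p: f * n for p, f in zip(PARTITIONS, fractions)}
    filled = {p: 0 for p in PARTITIONS}
    assignment: dict[str, str] = {}
    for _, members in ordered:
        part = max(PARTITIONS, key=lambda p: targets[p] - filled[p])
        for mol_id in members:
            assignment[mol_id] = part
        filled[part] += len(members)
    return SplitSpec("scaffold", fractions, seed, assignment)


def random_split(
    graphs: list[MolecularGraph],
    fractions=(0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitSpec:
    """Molecule-level random split with seeded shuffling."""
    if not graphs:
        raise ValueError("cannot split an empty dataset")
    fractions = _check_fractions(fractions)
    mol_ids = list(_molecule_table(graphs))
    rng = np.random.default_rng(seed)
    rng.shuffle(mol_ids)
    n = len(mol_ids)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    assignment = {}
    for k, mol_id in enumerate(mol_ids):
        if k < n_train:
            assignment[mol_id] = "train"
        elif k < n_train + n_valid:
            assignment[mol_id] = "valid"
        else:
            assignment[mol_id] = "test"
    return SplitSpec("random", fractions, seed, assignment)


# ------------------------------------------------------------------- batches
def make_batches(
    graphs: list[MolecularGraph], node_budget: int, include_coords: bool
) -> list[GraphBatch]:
    """Greedy batching under a per-batch node-count budget (dynamic sizing)."""
    batches, current, nodes = [], [], 0
    for g in graphs:
        if current and nodes + g.n_atoms > node_budget:
            batches.append(batch_graphs(current, include_coords))
            current, nodes = [], 0
        current.append(g)
        nodes += g.n_atoms
    if current:
        batches.append(batch_graphs(current, include_coords))
    return batches


def masked_loss(logits: Tensor, labels: np.ndarray, label_mask: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over observed labels; masked entries
    contribute exactly zero to value and gradient."""
    if np.sum(label_mask) == 0:
        raise ValueError("all labels in the batch are masked")
    return bce_with_logits(logits, labels, label_mask)


# ----------------------------------------------------------------- optimizer
class AdamW:
    """Adam with decoupled weight decay (bias-corrected moments)."""

    def __init__(
        self,
        params: list[tuple[str, Tensor]],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = {name: np.zeros_like(p.data) for name, p in params}
        self.v = {name: np.zeros_like(p.data) for name, p in params}

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            p.data -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )


# -------------------------------------------------------------- configuration
@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    max_epochs: int = 1000
    patience: int = 50
    node_budget: int = 2000  # dynamic batch sizing: nodes per batch
    monitor_metric: str = "roc_auc"
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if not self.patience < self.max_epochs:
            raise ConfigError("patience must be smaller than max_epochs")


class EarlyStopper:
    """Track the best monitored value; stop after `patience` stale epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -math.inf
        self.best_epoch: int | None = None
        self.best_state: dict | None = None
        self.stale = 0

    def update(self, metric: float, epoch: int, state: dict) -> bool:
        """Record epoch result; returns True when training should stop."""
        if metric > self.best:
            self.best, self.best_epoch, self.best_state = metric, epoch, state
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


# ------------------------------------------------------------------- metrics
@dataclass
class MetricsReport:
    """The eight classification metrics plus class counts.

    Ranking metrics are NaN (undefined), never zero, when the evaluated
    labels contain a single class.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc_roc: float
    f1: float
    balanced_accuracy: float
    auc_pr: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc_roc": self.auc_roc,
            "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy,
            "auc_pr": self.auc_pr,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def compute_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Threshold-0.5 confusion metrics plus trapezoidal ROC-AUC and
    step-interpolated AUC-PR on the raw scores."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    n = n_pos + n_neg
    accuracy = (tp + tn) / n if n else math.nan
    sensitivity = tp / n_pos if n_pos else math.nan
    specificity = tn / n_neg if n_neg else math.nan
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else math.nan
    balanced = (
        (sensitivity + specificity) / 2
        if not (math.isnan(sensitivity) or math.isnan(specificity))
        else math.nan
    )
    if n_pos and n_neg:
        auc_roc = float(roc_auc_score(y, s))
        auc_pr = float(average_precision_score(y, s))
    else:
        auc_roc = auc_pr = math.nan
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        mcc=mcc,
        auc_roc=auc_roc,
        f1=f1,
        balanced_accuracy=balanced,
        auc_pr=auc_pr,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def aggregate_by_molecule(
    graphs: list[MolecularGraph], scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Collapse per-record scores to per-molecule means.

    Returns (labels (M, T), masks (M, T), scores (M, T), mol_ids); a
    molecule's label comes from its first record.
    """
    order: list[str] = []
    by_mol: dict[str, list[int]] = {}
    for k, g in enumerate(graphs):
        if g.mol_id not in by_mol:
            by_mol[g.mol_id] = []
            order.append(g.mol_id)
        by_mol[g.mol_id].append(k)
    first = {m: idxs[0] for m, idxs in by_mol.items()}
    labels = np.stack([graphs[first[m]].labels for m in order])
    masks = np.stack([graphs[first[m]].label_mask for m in order])
    agg = np.stack([scores[by_mol[m]].mean(axis=0) for m in order])
    return labels, masks, agg, order


def evaluate(
    model: HybridGNN, graphs: list[MolecularGraph], node_budget: int = 2000
) -> MetricsReport:
    """Eight-metric report on a partition, aggregated per molecule.

    Multi-task inputs are macro-averaged over tasks with both classes
    observed; count fields are summed over tasks.
    """
    if not graphs:
        raise ValueError("cannot evaluate an empty partition")
    scores = model.predict_scores(graphs, node_budget)
    labels, masks, agg, _ = aggregate_by_molecule(graphs, scores)
    reports = []
    for t in range(labels.shape[1]):
        obs = masks[:, t] > 0
        if obs.sum() == 0:
            continue
        reports.append(compute_metrics(labels[obs, t], agg[obs, t]))
    if not reports:
        raise ValueError("no observed labels to evaluate")
    if len(reports) == 1:
        return reports[0]

    def macro(attr):
        vals = [getattr(r, attr) for r in reports]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    return MetricsReport(
        accuracy=macro("accuracy"),
        sensitivity=macro("sensitivity"),
        specificity=macro("specificity"),
        mcc=macro("mcc"),
        auc_roc=macro("auc_roc"),
        f1=macro("f1"),
        balanced_accuracy=macro("balanced_accuracy"),
        auc_pr=macro("auc_pr"),
        n_pos=sum(r.n_pos for r in reports),
        n_neg=sum(r.n_neg for r in reports),
    )


def _validation_metric(model: HybridGNN, graphs: list[MolecularGraph], node_budget: int) -> float:
    """Macro ROC-AUC over tasks on per-molecule aggregated scores."""
    scores = model.predict_scores(graphs, node_budget)
    labels, masks, agg, _ = aggregate_by_molecule(graphs, scores)
    aucs = []
    for t in range(labels.shape[1]):
        obs = masks[:, t] > 0
        y = labels[obs, t]
        if obs.sum() and 0 < y.sum() < obs.sum():
            aucs.append(roc_auc_score(y, agg[obs, t]))
    return float(np.mean(aucs)) if aucs else math.nan


# -------------------------------------------------------------------- training
def train(
    model: HybridGNN,
    train_graphs: list[MolecularGraph],
    valid_graphs: list[MolecularGraph],
    config: TrainConfig,
    monitor_fn=None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Optimize with AdamW + early stopping on the monitored metric.

    `monitor_fn(model, epoch) -> float` overrides the default validation
    ROC-AUC monitor. Returns (best parameter state, per-epoch history);
    the best state is also loaded back into the model. Epochs are 1-based.
    """
    if not train_graphs or (monitor_fn is None and not valid_graphs):
        raise ValueError("train and validation partitions must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(
        model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    stopper = EarlyStopper(config.patience)
    include_coords = model.config.wants_coords
    history = []
    order = np.arange(len(train_graphs))
    for epoch in range(1, config.max_epochs + 1):
        rng.shuffle(order)
        epoch_graphs = [train_graphs[i] for i in order]
        losses = []
        for batch in make_batches(epoch_graphs, config.node_budget, include_coords):
            logits, _ = model.forward(batch, training=True, rng=rng)
            loss = masked_loss(logits, batch.labels, batch.label_mask)
            if not np.isfinite(loss.data):
                raise NumericError(
                    f"non-finite loss at epoch {epoch}"
                    f" (last finite epoch losses: {losses[-3:]})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if monitor_fn is not None:
            metric = float(monitor_fn(model, epoch))
        else:
            metric = _validation_metric(model, valid_graphs, config.node_budget)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_metric": metric}
        )
        if stopper.update(metric, epoch, model.state_dict()):
            break
    best_state = stopper.best_state if stopper.best_state is not None else model.state_dict()
    model.load_state_dict(best_state)
    return best_state, pd.DataFrame(history)
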