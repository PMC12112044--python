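"""The hybrid graph neural network and its ablation/baseline variants.

The full architecture is a fixed MPNN → GAT×3 → GraphSAGE sequence over
heavy-atom molecular graphs, followed by global average pooling and a linear
task head:

* MPNN layer:      h_i' = σ(W h_i + Σ_{j∈N(i)} M(h_i, h_j)), with the
  message function M a one-hidden-layer MLP on the concatenation [h_i ‖ h_j].
* GAT layer:       e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j]), α_ij = softmax_j(e_ij),
  h_i' = σ(Σ_j α_ij W h_j), with 8 attention heads. Heads are concatenated in
  all but the last GAT layer, which averages them. A transient self-loop is
  added inside the attention computation so every softmax has support.
* GraphSAGE layer: h_i' = σ(W h_i + (1/|N(i)|) Σ_{j∈N(i)} W h_j)
  (full-neighborhood mean, no sampling; an empty neighborhood contributes
  the zero vector).

Ablation variants drop a named stage; baseline variants stack five copies of
a single layer type (MPNN / GAT / SAGE / GCN). 3D coordinates, when the
variant uses them, enter as three extra node-feature columns — there is no
distance-based edge reweighting.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import zipfile
from dataclasses import dataclass

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigError, ShapeError
from .molgraph import MolecularGraph

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "GraphBatch",
    "batch_graphs",
    "mpnn_forward",
    "gat_forward",
    "sage_forward",
    "gcn_forward",
    "readout",
    "HybridGNN",
    "make_variant",
]

VARIANTS = (
    "full",
    "smiles_only",
    "no_mpnn",
    "no_gat",
    "no_sage",
    "baseline_mpnn5",
    "baseline_gat5",
    "baseline_sage5",
    "baseline_gcn5",
)

_ACTIVATIONS = {
    "relu": ad.relu,
    "leaky_relu": ad.leaky_relu,
    "tanh": ad.tanh,
    "identity": lambda t: t,
}


@dataclass
class ModelConfig:
    """Architecture settings; `variant` selects the ablation/baseline."""

    variant: str = "full"
    hidden_dim: int = 64
    n_gat_layers: int = 3
    n_heads: int = 8
    n_tasks: int = 1
    dropout: float = 0.0
    activation: str = "relu"
    leaky_slope: float = 0.2
    message_hidden_dim: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.n_heads < 1:
            raise ConfigError("n_heads must be ≥ 1")
        if self.hidden_dim % self.n_heads != 0:
            raise ConfigError(
                "hidden_dim must be divisible by n_heads for concatenated heads"
            )
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must lie in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ConfigError(f"unknown activation {self.activation!r}")

    @property
    def wants_coords(self) -> bool:
        return self.variant != "smiles_only"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ------------------------------------------------------------------- batching
@dataclass
class GraphBatch:
    """A block-diagonal concatenation of molecular graphs."""

    x: np.ndarray  # (N, d) node features (coords appended when used)
    edge_index: np.ndarray  # (E, 2)
    graph_id: np.ndarray  # (N,) node → graph assignment
    n_graphs: int
    labels: np.ndarray  # (G, T)
    label_mask: np.ndarray  # (G, T)
    mol_ids: list[str]

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]


def batch_graphs(graphs: list[MolecularGraph], include_coords: bool) -> GraphBatch:
    if not graphs:
        raise ValueError("cannot batch an empty graph list")
    xs, edges, gids, labels, masks, ids = [], [], [], [], [], []
    offset = 0
    for g, graph in enumerate(graphs):
        if graph.n_atoms == 0:
            raise ValueError(f"graph {graph.mol_id!r} has no atoms")
        x = graph.node_features
        if include_coords:
            if graph.coords is None:
                raise ConfigError(
                    f"variant requires 3D coordinates but {graph.mol_id!r} has none"
                )
            x = np.concatenate([x, graph.coords], axis=1)
        xs.append(x)
        if len(graph.edge_index):
            edges.append(np.asarray(graph.edge_index) + offset)
        gids.append(np.full(graph.n_atoms, g, dtype=np.int64))
        labels.append(graph.labels)
        masks.append(graph.label_mask)
        ids.append(graph.mol_id)
        offset += graph.n_atoms
    return GraphBatch(
        x=np.concatenate(xs, axis=0),
        edge_index=np.concatenate(edges, axis=0)
        if edges
        else np.zeros((0, 2), dtype=np.int64),
        graph_id=np.concatenate(gids),
        n_graphs=len(graphs),
        labels=np.stack(labels),
        label_mask=np.stack(masks),
        mol_ids=ids,
    )


# ------------------------------------------------------------ layer forwards
def _act(name: str):
    return _ACTIVATIONS[name]


def mpnn_forward(
    h: Tensor,
    edge_index: np.ndarray,
    params: dict[str, Tensor],
    activation: str = "relu",
) -> Tensor:
    """Message-passing update: h_i' = σ(W h_i + b + Σ_{j∈N(i)} M(h_i, h_j)).

    The message MLP reads the concatenation [h_i ‖ h_j] for each directed
    edge (i, j) and its output is summed into node i. Isolated nodes receive
    only the self term.
    """
    n = h.shape[0]
    self_term = h @ params["W"] + params["b"]
    if len(edge_index):
        src, nbr = edge_index[:, 0], edge_index[:, 1]
        pair = ad.concat([h[src], h[nbr]], axis=1)
        msg = ad.relu(pair @ params["M1"] + params["bm1"]) @ params["M2"] + params["bm2"]
        self_term = self_term + ad.segment_sum(msg, src, n)
    return _act(activation)(self_term)


def _segment_max(values: np.ndarray, seg: np.ndarray, n: int) -> np.ndarray:
    out = np.full((n,) + values.shape[1:], -np.inf)
    np.maximum.at(out, seg, values)
    return out


def gat_forward(
    h: Tensor,
    edge_index: np.ndarray,
    n_nodes: int,
    params: dict[str, Tensor],
    n_heads: int = 8,
    concat_heads: bool = True,
    leaky_slope: float = 0.2,
    activation: str = "relu",
):
    """Multi-head graph attention.

    Per head: e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j]), α_ij = softmax over
    j ∈ N(i) ∪ {i} (a transient self-loop guarantees nonempty support),
    h_i' = σ(Σ_j α_ij W h_j). Heads are concatenated or averaged.

    Returns (output embeddings, attention weights (E_sl, n_heads) ndarray,
    self-loop-augmented edge array (E_sl, 2)).
    """
    loops = np.stack([np.arange(n_nodes)] * 2, axis=1)
    edges_sl = (
        np.concatenate([np.asarray(edge_index), loops], axis=0)
        if len(edge_index)
        else loops
    )
    src, nbr = edges_sl[:, 0], edges_sl[:, 1]
    dh = params["a_src"].shape[1]
    wh = (h @ params["W"]).reshape(n_nodes, n_heads, dh)
    s_src = (wh * params["a_src"]).sum(axis=2)  # (N, heads)
    s_nbr = (wh * params["a_dst"]).sum(axis=2)
    logits = ad.leaky_relu(s_src[src] + s_nbr[nbr], leaky_slope)  # (E_sl, heads)
    # softmax over the neighborhood of each attending node, per head; the
    # max shift is attention-invariant so it is safely treated as constant
    shift = _segment_max(logits.data, src, n_nodes)
    z = ad.exp(logits - Tensor(shift[src]))
    denom = ad.segment_sum(z, src, n_nodes)
    alpha = z / denom[src]  # (E_sl, heads)
    contrib = alpha.reshape(-1, n_heads, 1) * wh[nbr]
    agg = ad.segment_sum(contrib, src, n_nodes)  # (N, heads, dh)
    if concat_heads:
        out = agg.reshape(n_nodes, n_heads * dh)
    else:
        out = agg.mean(axis=1)
    out = _act(activation)(out + params["b"])
    return out, alpha.data, edges_sl


def sage_forward(
    h: Tensor,
    edge_index: np.ndarray,
    params: dict[str, Tensor],
    activation: str = "relu",
) -> Tensor:
    """Mean-aggregation update: h_i' = σ(W h_i + (1/|N(i)|) Σ_j W h_j + b).

    One weight matrix serves both the self and the neighbor terms; an empty
    neighborhood contributes the zero vector.
    """
    n = h.shape[0]
    wh = h @ params["W"]
    out = wh + params["b"]
    if len(edge_index):
        src, nbr = edge_index[:, 0], edge_index[:, 1]
        deg = np.bincount(src, minlength=n).astype(np.float64)
        agg = ad.segment_sum(wh[nbr], src, n)
        out = out + agg * (1.0 / np.maximum(deg, 1.0))[:, None]
    return _act(activation)(out)


def gcn_forward(
    h: Tensor,
    edge_index: np.ndarray,
    params: dict[str, Tensor],
    activation: str = "relu",
) -> Tensor:
    """Symmetric-normalized graph convolution with self-loops (baseline)."""
    n = h.shape[0]
    loops = np.stack([np.arange(n)] * 2, axis=1)
    edges_sl = (
        np.concatenate([np.asarray(edge_index), loops], axis=0)
        if len(edge_index)
        else loops
    )
    src, nbr = edges_sl[:, 0], edges_sl[:, 1]
    deg = np.bincount(src, minlength=n).astype(np.float64)
    coef = 1.0 / np.sqrt(deg[src] * deg[nbr])
    wh = h @ params["W"]
    agg = ad.segment_sum(wh[nbr] * coef[:, None], src, n)
    return _act(activation)(agg + params["b"])


def readout(h: Tensor, graph_id: np.ndarray, n_graphs: int, params: dict[str, Tensor]) -> Tensor:
    """Global average pooling per graph followed by the linear task head."""
    counts = np.bincount(graph_id, minlength=n_graphs).astype(np.float64)
    if np.any(counts == 0):
        raise ValueError("batch contains an empty graph")
    pooled = ad.segment_sum(h, graph_id, n_graphs) * (1.0 / counts)[:, None]
    return pooled @ params["W"] + params["b"]


# --------------------------------------------------------------- the network
def _glorot(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


def _init_layer(kind: str, d_in: int, d_out: int, cfg: ModelConfig, rng) -> dict[str, Tensor]:
    P = lambda a: Tensor(a, requires_grad=True)
    if kind == "mpnn":
        m = cfg.message_hidden_dim
        return {
            "W": P(_glorot(rng, d_in, d_out)),
            "b": P(np.zeros(d_out)),
            "M1": P(_glorot(rng, 2 * d_in, m)),
            "bm1": P(np.zeros(m)),
            "M2": P(_glorot(rng, m, d_out)),
            "bm2": P(np.zeros(d_out)),
        }
    if kind in ("sage", "gcn"):
        return {"W": P(_glorot(rng, d_in, d_out)), "b": P(np.zeros(d_out))}
    if kind == "readout":
        return {"W": P(_glorot(rng, d_in, d_out)), "b": P(np.zeros(d_out))}
    raise ConfigError(f"unknown layer kind {kind!r}")


def _init_gat(d_in: int, d_out: int, concat: bool, cfg: ModelConfig, rng) -> dict[str, Tensor]:
    P = lambda a: Tensor(a, requires_grad=True)
    heads = cfg.n_heads
    dh = d_out // heads if concat else d_out
    return {
        "W": P(_glorot(rng, d_in, heads * dh)),
        "a_src": P(_glorot(rng, heads, dh) / np.sqrt(dh)),
        "a_dst": P(_glorot(rng, heads, dh) / np.sqrt(dh)),
        "b": P(np.zeros(d_out)),
    }


def _layer_plan(cfg: ModelConfig, in_dim: int) -> list[tuple[str, str, int, int, dict]]:
    """List of (name, kind, d_in, d_out, extras) composing the variant."""
    H = cfg.hidden_dim
    plan: list[tuple[str, str, int, int, dict]] = []
    d = in_dim

    def add(kind: str, d_out: int, **extra):
        nonlocal d
        plan.append((f"{kind}{sum(1 for p in plan if p[1] == kind)}", kind, d, d_out, extra))
        d = d_out

    def gat_stack(n_layers: int):
        for k in range(n_layers):
            add("gat", H, concat=(k < n_layers - 1))

    v = cfg.variant
    if v in ("full", "smiles_only"):
        add("mpnn", H)
        gat_stack(cfg.n_gat_layers)
        add("sage", H)
    elif v == "no_mpnn":
        gat_stack(cfg.n_gat_layers)
        add("sage", H)
    elif v == "no_gat":
        add("mpnn", H)
        add("sage", H)
    elif v == "no_sage":
        add("mpnn", H)
        gat_stack(cfg.n_gat_layers)
    elif v.startswith("baseline_"):
        kind = {"baseline_mpnn5": "mpnn", "baseline_gat5": "gat",
                "baseline_sage5": "sage", "baseline_gcn5": "gcn"}[v]
        for k in range(5):
            if kind == "gat":
                add("gat", H, concat=(k < 4))
            else:
                add(kind, H)
    plan.append(("readout", "readout", d, cfg.n_tasks, {}))
    return plan


class HybridGNN:
    """The assembled network: a layer plan plus its parameter tensors."""

    def __init__(self, config: ModelConfig, in_dim: int, params=None):
        self.config = config
        self.in_dim = in_dim
        self.plan = _layer_plan(config, in_dim)
        rng = np.random.default_rng(config.seed)
        if params is None:
            params = {}
            for name, kind, d_in, d_out, extra in self.plan:
                if kind == "gat":
                    params[name] = _init_gat(d_in, d_out, extra["concat"], config, rng)
                else:
                    params[name] = _init_layer(kind, d_in, d_out, config, rng)
        self.params: dict[str, dict[str, Tensor]] = params

    # ------------------------------------------------------------- plumbing
    def parameters(self) -> list[tuple[str, Tensor]]:
        return [
            (f"{layer}.{key}", t)
            for layer, group in self.params.items()
            for key, t in group.items()
        ]

    def n_parameters(self) -> int:
        return sum(t.data.size for _, t in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.parameters():
            if name not in state:
                raise ConfigError(f"checkpoint is missing parameter {name!r}")
            if state[name].shape != t.data.shape:
                raise ShapeError(
                    f"parameter {name!r} shape {state[name].shape} != {t.data.shape}"
                )
            t.data = np.asarray(state[name], dtype=np.float64).copy()

    # -------------------------------------------------------------- forward
    def forward(
        self,
        batch: GraphBatch,
        collect_attention: bool = False,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Run the layer plan; returns (logits Tensor, attention list).

        Attention entries are (gat_layer_index, weights (E_sl, heads),
        self-loop-augmented edges (E_sl, 2)); weights are detached arrays.
        """
        if batch.x.shape[1] != self.in_dim:
            raise ShapeError(
                f"batch feature dim {batch.x.shape[1]} != model in_dim {self.in_dim}"
            )
        cfg = self.config
        h = Tensor(batch.x)
        attention = []
        gat_idx = 0
        for name, kind, _, _, extra in self.plan:
            p = self.params[name]
            if kind == "mpnn":
                h = mpnn_forward(h, batch.edge_index, p, cfg.activation)
            elif kind == "gat":
                h, alpha, edges_sl = gat_forward(
                    h,
                    batch.edge_index,
                    batch.n_nodes,
                    p,
                    n_heads=cfg.n_heads,
                    concat_heads=extra["concat"],
                    leaky_slope=cfg.leaky_slope,
                    activation=cfg.activation,
                )
                if collect_attention:
                    attention.append((gat_idx, alpha, edges_sl))
                gat_idx += 1
            elif kind == "sage":
                h = sage_forward(h, batch.edge_index, p, cfg.activation)
            elif kind == "gcn":
                h = gcn_forward(h, batch.edge_index, p, cfg.activation)
            elif kind == "readout":
                return readout(h, batch.graph_id, batch.n_graphs, p), attention
            if training and cfg.dropout > 0:
                if rng is None:
                    rng = np.random.default_rng(cfg.seed)
                keep = (rng.random(h.shape) >= cfg.dropout) / (1 - cfg.dropout)
                h = h * Tensor(keep)
        raise AssertionError("layer plan ended without a readout")  # pragma: no cover

    def predict_scores(self, graphs: list[MolecularGraph], node_budget: int = 2000) -> np.ndarray:
        """Sigmoid task scores per input record, batched by node budget."""
        from .training import make_batches  # local import to avoid a cycle

        scores = []
        for chunk in make_batches(graphs, node_budget, self.config.wants_coords):
            logits, _ = self.forward(chunk)
            scores.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(scores, axis=0)

    # ----------------------------------------------------------- checkpoint
    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Single-archive checkpoint: config JSON + parameter tensors."""
        meta = {
            "format_version": self.FORMAT_VERSION,
            "in_dim": self.in_dim,
            "config": self.config.to_dict(),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            buf = _io.BytesIO()
            np.savez(buf, **self.state_dict())
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "HybridGNN":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format_version") != cls.FORMAT_VERSION:
                raise ConfigError(
                    f"unsupported checkpoint format {meta.get('format_version')!r}"
                )
            with np.load(_io.BytesIO(zf.read("params.npz"))) as npz:
                state = {k: npz[k] for k in npz.files}
        model = cls(ModelConfig.from_dict(meta["config"]), meta["in_dim"])
        model.load_state_dict(state)
        return model


def make_variant(config: ModelConfig, in_dim: int) -> HybridGNN:
    """Factory: seeded, reproducible initialization of any variant."""
    return HybridGNN(config, in_dim)
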