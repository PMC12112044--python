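"""Layer equations against brute-force oracles, and architectural contracts."""

import numpy as np
import pytest

from oracles import gat_oracle, gcn_oracle, mpnn_oracle, sage_oracle
from payloadgnn.autodiff import Tensor
from payloadgnn.errors import ConfigError
from payloadgnn.model import (
    VARIANTS,
    HybridGNN,
    ModelConfig,
    batch_graphs,
    gat_forward,
    gcn_forward,
    make_variant,
    mpnn_forward,
    readout,
    sage_forward,
)
from payloadgnn.molgraph import MolecularGraph
from payloadgnn.synthetic import generate_random_graphs


def _params_for(kind, d_in, d_out, seed, heads=4, concat=True):
    cfg = ModelConfig(hidden_dim=heads * 4, n_heads=heads, seed=seed, message_hidden_dim=6)
    from payloadgnn.model import _init_gat, _init_layer

    rng = np.random.default_rng(seed)
    if kind == "gat":
        return _init_gat(d_in, d_out, concat, cfg, rng)
    return _init_layer(kind, d_in, d_out, cfg, rng)


@pytest.mark.parametrize("seed", range(8))
def test_mpnn_matches_brute_force(seed):
    (g,) = generate_random_graphs(1, (2, 9), 5, seed=seed + 100)
    params = _params_for("mpnn", 5, 7, seed)
    got = mpnn_forward(Tensor(g.node_features), g.edge_index, params).data
    want = mpnn_oracle(g.node_features, g.edge_index, params)
    np.testing.assert_allclose(got, want, atol=1e-10)


@pytest.mark.parametrize("seed,concat", [(s, c) for s in range(6) for c in (True, False)])
def test_gat_matches_brute_force(seed, concat):
    (g,) = generate_random_graphs(1, (2, 8), 5, seed=seed + 200)
    d_out = 8
    params = _params_for("gat", 5, d_out, seed, heads=4, concat=concat)
    got, alpha, edges_sl = gat_forward(
        Tensor(g.node_features), g.edge_index, g.n_atoms, params,
        n_heads=4, concat_heads=concat,
    )
    want, alpha_want = gat_oracle(g.node_features, g.edge_index, params, 4, concat)
    np.testing.assert_allclose(got.data, want, atol=1e-10)
    for e, (i, j) in enumerate(edges_sl):
        for h in range(4):
            assert alpha[e, h] == pytest.approx(alpha_want[(i, j, h)], abs=1e-10)


@pytest.mark.parametrize("seed", range(8))
def test_sage_matches_brute_force(seed):
    (g,) = generate_random_graphs(1, (2, 9), 5, seed=seed + 300)
    params = _params_for("sage", 5, 6, seed)
    got = sage_forward(Tensor(g.node_features), g.edge_index, params).data
    np.testing.assert_allclose(got, sage_oracle(g.node_features, g.edge_index, params), atol=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_gcn_matches_brute_force(seed):
    (g,) = generate_random_graphs(1, (2, 9), 5, seed=seed + 400)
    params = _params_for("gcn", 5, 6, seed)
    got = gcn_forward(Tensor(g.node_features), g.edge_index, params).data
    np.testing.assert_allclose(got, gcn_oracle(g.node_features, g.edge_index, params), atol=1e-10)


# --------------------------------------------------------------- closed forms
def test_mpnn_single_node_identity():
    params = _params_for("mpnn", 4, 4, 0)
    params["W"].data = np.eye(4)
    params["b"].data[:] = 0.0
    h = np.abs(np.random.default_rng(1).normal(size=(1, 4)))  # positive → ReLU-transparent
    out = mpnn_forward(Tensor(h), np.zeros((0, 2), dtype=int), params)
    np.testing.assert_allclose(out.data, h, atol=1e-12)


def test_gat_equal_features_give_uniform_attention():
    # identical neighbor features ⇒ equal logits ⇒ α = 1/|N(i)∪{i}|
    h = np.ones((4, 5))
    edges = np.array([[0, 1], [1, 0], [1, 2], [2, 1], [2, 3], [3, 2]])
    params = _params_for("gat", 5, 8, 3, heads=4)
    _, alpha, edges_sl = gat_forward(Tensor(h), edges, 4, params, n_heads=4)
    src = edges_sl[:, 0]
    for i in range(4):
        sel = src == i
        np.testing.assert_allclose(alpha[sel], 1.0 / sel.sum(), atol=1e-12)


def test_sage_identical_features_double_with_identity_weights():
    h = np.tile(np.array([0.5, 1.5, 2.0]), (3, 1))
    edges = np.array([[0, 1], [1, 0], [1, 2], [2, 1]])
    params = _params_for("sage", 3, 3, 0)
    params["W"].data = np.eye(3)
    params["b"].data[:] = 0.0
    out = sage_forward(Tensor(h), edges, params, activation="identity")
    np.testing.assert_allclose(out.data, 2 * h, atol=1e-12)


def test_sage_isolated_node_gets_only_self_term():
    params = _params_for("sage", 3, 3, 0)
    h = np.array([[1.0, -2.0, 0.5]])
    out = sage_forward(Tensor(h), np.zeros((0, 2), dtype=int), params)
    expect = np.maximum(h @ params["W"].data + params["b"].data, 0)
    np.testing.assert_allclose(out.data, expect, atol=1e-12)


def test_readout_identical_rows_pool_to_the_row(rng):
    u = rng.normal(size=4)
    h = Tensor(np.tile(u, (5, 1)))
    params = {"W": Tensor(np.eye(4)), "b": Tensor(np.zeros(4))}
    out = readout(h, np.zeros(5, dtype=int), 1, params)
    np.testing.assert_allclose(out.data[0], u, atol=1e-12)


def test_readout_zero_weights_return_bias(rng):
    h = Tensor(rng.normal(size=(6, 4)))
    params = {"W": Tensor(np.zeros((4, 2))), "b": Tensor(np.array([0.3, -0.7]))}
    out = readout(h, np.array([0, 0, 0, 1, 1, 1]), 2, params)
    np.testing.assert_allclose(out.data, [[0.3, -0.7], [0.3, -0.7]], atol=1e-12)


def test_readout_rejects_empty_graph(rng):
    with pytest.raises(ValueError):
        readout(Tensor(rng.normal(size=(2, 3))), np.array([0, 2]), 3,
                {"W": Tensor(np.zeros((3, 1))), "b": Tensor(np.zeros(1))})


# ----------------------------------------------------------------- invariants
def _permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    inv = np.argsort(perm)
    edge = inv[np.asarray(g.edge_index)] if len(g.edge_index) else g.edge_index
    return MolecularGraph(
        node_features=g.node_features[perm],
        edge_index=edge,
        coords=None if g.coords is None else g.coords[perm],
        labels=g.labels,
        label_mask=g.label_mask,
        mol_id=g.mol_id,
        smiles=g.smiles,
    )


@pytest.mark.parametrize("variant", VARIANTS)
def test_graph_logits_invariant_under_node_relabeling(variant, small_graphs, rng):
    cfg = ModelConfig(variant=variant, hidden_dim=16, n_heads=4, seed=5,
                      message_hidden_dim=8)
    graphs = [g for g in small_graphs[:5]]
    coords = cfg.wants_coords
    if coords:
        graphs = [
            g.with_coords(rng.normal(size=(g.n_atoms, 3))) for g in graphs
        ]
    model = make_variant(cfg, 5 + (3 if coords else 0))
    base, _ = model.forward(batch_graphs(graphs, coords))
    for g in graphs:
        perm = rng.permutation(g.n_atoms)
        permuted, _ = model.forward(batch_graphs([_permute_graph(g, perm)], coords))
        orig, _ = model.forward(batch_graphs([g], coords))
        np.testing.assert_allclose(permuted.data, orig.data, atol=1e-5)


def test_attention_rows_sum_to_one(small_graphs):
    cfg = ModelConfig(hidden_dim=16, n_heads=8, seed=2, message_hidden_dim=8)
    model = make_variant(cfg, 5)
    batch = batch_graphs(list(small_graphs), include_coords=False)
    _, attention = model.forward(batch, collect_attention=True)
    assert len(attention) == cfg.n_gat_layers
    for _, alpha, edges_sl in attention:
        sums = np.zeros((batch.n_nodes, alpha.shape[1]))
        np.add.at(sums, edges_sl[:, 0], alpha)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)


def test_attention_aggregation_is_convex_combination(rng):
    # pre-activation output per head must be Σ α_ij W h_j with α a simplex:
    # checked directly by reconstructing the aggregation from emitted α.
    (g,) = generate_random_graphs(1, (5, 8), 5, seed=77)
    params = _params_for("gat", 5, 8, 9, heads=4)
    out, alpha, edges_sl = gat_forward(
        Tensor(g.node_features), g.edge_index, g.n_atoms, params,
        n_heads=4, concat_heads=True, activation="identity",
    )
    assert np.all(alpha >= 0) and np.all(alpha <= 1 + 1e-12)
    wh = (g.node_features @ params["W"].data).reshape(g.n_atoms, 4, 2)
    recon = np.zeros((g.n_atoms, 4, 2))
    for e, (i, j) in enumerate(edges_sl):
        recon[i] += alpha[e][:, None] * wh[j]
    np.testing.assert_allclose(
        out.data, recon.reshape(g.n_atoms, 8) + params["b"].data, atol=1e-10
    )


def test_smiles_only_is_coordinate_blind(small_graphs, rng):
    cfg = ModelConfig(variant="smiles_only", hidden_dim=16, n_heads=4, seed=4,
                      message_hidden_dim=8)
    model = make_variant(cfg, 5)
    graphs = [g.with_coords(rng.normal(size=(g.n_atoms, 3))) for g in small_graphs[:6]]
    a, _ = model.forward(batch_graphs(graphs, include_coords=False))
    moved = [g.with_coords(g.coords + rng.normal(size=g.coords.shape)) for g in graphs]
    b, _ = model.forward(batch_graphs(moved, include_coords=False))
    np.testing.assert_array_equal(a.data, b.data)  # bit-identical


def test_full_variant_requires_coords(small_graphs):
    cfg = ModelConfig(variant="full", hidden_dim=16, n_heads=4, seed=4,
                      message_hidden_dim=8)
    with pytest.raises(ConfigError):
        batch_graphs(list(small_graphs[:2]), include_coords=cfg.wants_coords)


# -------------------------------------------------------------------- factory
def test_variant_factory_is_seed_deterministic():
    cfg = ModelConfig(hidden_dim=16, n_heads=4, seed=123, message_hidden_dim=8)
    a, b = make_variant(cfg, 8), make_variant(cfg, 8)
    for (n1, p1), (n2, p2) in zip(a.parameters(), b.parameters()):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)


def test_full_has_more_parameters_than_ablations():
    kwargs = dict(hidden_dim=16, n_heads=4, seed=0, message_hidden_dim=8)
    full = make_variant(ModelConfig(variant="full", **kwargs), 8)
    for variant in ("no_gat", "no_mpnn", "no_sage"):
        reduced = make_variant(ModelConfig(variant=variant, **kwargs), 8)
        assert full.n_parameters() > reduced.n_parameters()


def test_gcn_baseline_has_five_identical_layer_shapes():
    model = make_variant(
        ModelConfig(variant="baseline_gcn5", hidden_dim=16, n_heads=4, seed=0), 8
    )
    gcn_layers = [name for name, kind, *_ in model.plan if kind == "gcn"]
    assert len(gcn_layers) == 5
    shapes = {tuple(model.params[n]["W"].data.shape) for n in gcn_layers[1:]}
    assert shapes == {(16, 16)}


def test_unknown_variant_rejected():
    with pytest.raises(ConfigError):
        ModelConfig(variant="resnet50")


def test_checkpoint_roundtrip(tmp_path, small_graphs):
    cfg = ModelConfig(variant="smiles_only", hidden_dim=16, n_heads=4, seed=8,
                      message_hidden_dim=8)
    model = make_variant(cfg, 5)
    batch = batch_graphs(list(small_graphs[:4]), include_coords=False)
    before, _ = model.forward(batch)
    path = tmp_path / "model.ckpt"
    model.save(path)
    loaded = HybridGNN.load(path)
    after, _ = loaded.forward(batch)
    np.testing.assert_array_equal(before.data, after.data)
    assert loaded.config.variant == "smiles_only"
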