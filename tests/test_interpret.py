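"""Attention summaries and substructure attribution."""

import math

import numpy as np
import pytest

from payloadgnn.errors import CapabilityError, SmilesParseError
from payloadgnn.interpret import (
    AttentionRecord,
    atom_attention_scores,
    attribute_brics,
    attribute_murcko,
    attribute_smarts,
    collect_attention,
    motif_discrimination_test,
    ring_system_attribution,
    summarize_attention,
)
from payloadgnn.model import ModelConfig, make_variant
from payloadgnn.molgraph import build_graph


def _model(variant="smiles_only", heads=8, seed=0):
    cfg = ModelConfig(variant=variant, hidden_dim=16, n_heads=heads, seed=seed,
                      message_hidden_dim=8)
    return make_variant(cfg, 5)


def _uniform_records(graphs, n_heads=2, layer=0):
    """Hand-built records with uniform attention over each neighborhood."""
    records = []
    for g in graphs:
        nbrs = {i: [i] for i in range(g.n_atoms)}
        for i, j in g.edge_index:
            nbrs[int(i)].append(int(j))
        for i, targets in nbrs.items():
            for j in targets:
                for h in range(n_heads):
                    records.append(
                        AttentionRecord(g.mol_id, layer, h, (i, j), 1.0 / len(targets))
                    )
    return records


# ----------------------------------------------------------------- collection
def test_single_node_graph_gets_self_weight_one():
    model = _model()
    g = build_graph("C", mol_id="methane")
    records = collect_attention(model, [g])
    assert records and all(r.edge == (0, 0) and r.weight == pytest.approx(1.0)
                           for r in records)
    layers = {r.layer_index for r in records}
    heads = {r.head_index for r in records}
    assert layers == {0, 1, 2} and heads == set(range(8))


def test_star_graph_symmetric_leaves_get_equal_weights():
    model = _model()
    g = build_graph("CC(C)(C)C", mol_id="neopentane")  # central C + 4 methyl leaves
    records = collect_attention(model, [g])
    center = 1  # canonical order: central atom has degree 4
    deg = {i: 0 for i in range(g.n_atoms)}
    for i, _ in g.edge_index:
        deg[int(i)] += 1
    center = max(deg, key=deg.get)
    for layer in (0, 1, 2):
        for head in range(8):
            leaf_weights = [
                r.weight
                for r in records
                if r.layer_index == layer and r.head_index == head
                and r.edge[0] == center and r.edge[1] != center
            ]
            assert len(leaf_weights) == 4
            assert max(leaf_weights) - min(leaf_weights) < 1e-9


def test_collection_is_deterministic():
    model = _model()
    g = build_graph("CCOC(C)=O", mol_id="m")
    a = collect_attention(model, [g])
    b = collect_attention(model, [g])
    assert [(r.edge, r.weight) for r in a] == [(r.edge, r.weight) for r in b]


def test_no_gat_variant_raises_capability_error():
    model = _model(variant="no_gat")
    with pytest.raises(CapabilityError):
        collect_attention(model, [build_graph("CCO")])


def test_per_node_normalization_of_emitted_records():
    model = _model()
    g = build_graph("c1ccc2ccccc2c1O", mol_id="naphthol")
    records = collect_attention(model, [g])
    sums: dict[tuple, float] = {}
    for r in records:
        key = (r.layer_index, r.head_index, r.edge[0])
        sums[key] = sums.get(key, 0.0) + r.weight
    assert all(abs(v - 1.0) < 1e-6 for v in sums.values())


# ------------------------------------------------------------------ summaries
def test_uniform_head_importance_gives_effective_heads_eight():
    records = [
        AttentionRecord("m", 0, h, (0, 0), 0.125) for h in range(8)
    ]
    summary = summarize_attention(records)
    assert summary.layers[0].effective_heads == pytest.approx(8.0, abs=1e-12)


def test_one_hot_head_importance_gives_effective_heads_one():
    records = [AttentionRecord("m", 0, 0, (0, 0), 1.0)] + [
        AttentionRecord("m", 0, h, (0, 0), 0.0) for h in range(1, 8)
    ]
    summary = summarize_attention(records)
    assert summary.layers[0].effective_heads == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("k", [2, 8, 128])
def test_uniform_pooled_distribution_entropy_is_ln_k(k):
    records = [AttentionRecord("m", 0, 0, (i, 0), 1.0 / k) for i in range(k)]
    summary = summarize_attention(records)
    assert summary.layers[0].entropy == pytest.approx(math.log(k), abs=1e-12)


def test_pooled_distribution_is_renormalized_before_entropy():
    # raw weights summing to 3 must give the same entropy as the normalized set
    records = [AttentionRecord("m", 0, 0, (i, 0), 0.75) for i in range(4)]
    summary = summarize_attention(records)
    assert summary.layers[0].entropy == pytest.approx(math.log(4), abs=1e-12)
    assert summary.layers[0].mean == pytest.approx(0.75)


def test_effective_heads_bounds_on_model_output():
    model = _model()
    graphs = [build_graph(s, mol_id=s) for s in ["CCOC(C)=O", "c1ccccc1O", "CCNCC"]]
    summary = summarize_attention(collect_attention(model, graphs))
    for layer in summary.layers:
        assert 1.0 - 1e-9 <= layer.effective_heads <= 8.0 + 1e-9
        assert layer.entropy >= 0
        assert layer.head_importance.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- attribution
def test_ester_smarts_matches_methyl_acetate_once():
    g = build_graph("COC(C)=O", mol_id="methyl_acetate")
    records = _uniform_records([g])
    (attr,) = attribute_smarts([g], records, ["COC(=O)"])
    assert attr.n_molecules_matched == 1
    assert len(attr.matches["methyl_acetate"]) == 1


def test_hydroxyl_smarts_misses_benzene():
    g = build_graph("c1ccccc1", mol_id="benzene")
    (attr,) = attribute_smarts([g], _uniform_records([g]), ["C[OH]"])
    assert attr.n_molecules_matched == 0
    assert math.isnan(attr.mean_attention)


def test_invalid_smarts_names_the_pattern():
    g = build_graph("CCO", mol_id="m")
    with pytest.raises(SmilesParseError, match="not_smarts"):
        attribute_smarts([g], _uniform_records([g]), ["not_smarts("])


def test_uniform_attention_makes_all_attributions_equal():
    graphs = [
        build_graph(s, mol_id=f"m{i}")
        for i, s in enumerate(["COC(C)=O", "CCOC(=O)c1ccccc1", "CCCC(=O)OC"])
    ]
    # equal weight on every atom: a star-free uniform distribution per node
    records = []
    for g in graphs:
        for i in range(g.n_atoms):
            records.append(AttentionRecord(g.mol_id, 0, 0, (i, i), 0.5))
    values = [
        a.mean_attention
        for a in attribute_smarts(graphs, records, ["COC(=O)", "c1ccccc1", "C"])
        + attribute_brics(graphs, records)
        if a.n_molecules_matched
    ]
    assert max(values) - min(values) < 1e-9


def test_murcko_attribution_strips_side_chains():
    g = build_graph("Cc1ccccc1", mol_id="toluene")
    records = _uniform_records([g])
    attrs = attribute_murcko([g], records)
    (ring,) = [a for a in attrs if a.pattern]
    assert ring.pattern == "c1ccccc1"
    (match,) = ring.matches["toluene"]
    assert len(match) == 6  # methyl carbon excluded


def test_acyclic_molecule_has_empty_scaffold():
    g = build_graph("CCCCCC", mol_id="hexane")
    attrs = attribute_murcko([g], _uniform_records([g]))
    (empty,) = attrs
    assert empty.pattern == "" and empty.matches["hexane"] == []


def test_shared_scaffold_grouped_into_one_entry():
    graphs = [
        build_graph("Cc1ccccc1", mol_id="toluene"),
        build_graph("CCc1ccccc1", mol_id="ethylbenzene"),
    ]
    attrs = attribute_murcko(graphs, _uniform_records(graphs))
    (ring,) = [a for a in attrs if a.pattern == "c1ccccc1"]
    assert ring.n_molecules_matched == 2


def test_brics_on_methane_is_single_fragment():
    g = build_graph("C", mol_id="methane")
    (frag,) = attribute_brics([g], _uniform_records([g]))
    assert frag.matches["methane"] == [(0,)]


def test_brics_splits_ester_linkage_of_methyl_benzoate():
    g = build_graph("COC(=O)c1ccccc1", mol_id="mb")
    attrs = attribute_brics([g], _uniform_records([g]))
    all_atoms = sorted(a for attr in attrs for m in attr.matches.get("mb", []) for a in m)
    assert all_atoms == list(range(g.n_atoms))  # fragments partition the molecule
    assert len(attrs) >= 2


def test_cyclopentane_five_ring_detected():
    g = build_graph("C1CCCC1", mol_id="cyclopentane")
    attr = ring_system_attribution([g], _uniform_records([g]), ring_size=5)
    assert attr.n_molecules_matched == 1
    assert attr.matches["cyclopentane"] == [(0, 1, 2, 3, 4)]


def test_benzene_has_no_five_ring():
    g = build_graph("c1ccccc1", mol_id="benzene")
    attr = ring_system_attribution([g], _uniform_records([g]), ring_size=5)
    assert attr.n_molecules_matched == 0


def test_camptothecin_like_fused_system_contains_five_ring():
    # indolizine-like fused bicycle with a five-membered component
    g = build_graph("C1Cc2ccccc2C1", mol_id="indane")
    attr = ring_system_attribution([g], _uniform_records([g]), ring_size=5)
    assert attr.n_molecules_matched == 1


def test_atom_scores_average_incoming_weights_over_heads():
    records = [
        AttentionRecord("m", 2, 0, (0, 1), 0.4),
        AttentionRecord("m", 2, 1, (0, 1), 0.8),
        AttentionRecord("m", 2, 0, (1, 1), 0.6),
        AttentionRecord("m", 0, 0, (0, 1), 0.99),  # earlier layer ignored
    ]
    scores = atom_attention_scores(records)
    assert scores["m"][1] == pytest.approx((0.4 + 0.8 + 0.6) / 3, abs=1e-12)


def test_motif_discrimination_detects_planted_signal():
    graphs = [
        build_graph(s, mol_id=f"m{i}")
        for i, s in enumerate(
            ["COC(=O)CCCC", "CCCCOC(C)=O", "CCOC(=O)CC", "COC(=O)c1ccccc1",
             "CCCCCOC(C)=O", "CCC(=O)OCCC", "COC(=O)CCN", "CCOC(=O)CCC"]
        )
    ]
    query_atoms = {}
    records = []
    from rdkit import Chem

    patt = Chem.MolFromSmarts("COC(=O)")
    for g in graphs:
        mol = Chem.MolFromSmiles(g.smiles)
        motif = {a for m in mol.GetSubstructMatches(patt) for a in m}
        for i in range(g.n_atoms):
            w = 0.9 if i in motif else 0.1
            records.append(AttentionRecord(g.mol_id, 0, 0, (i, i), w))
    diffs, p = motif_discrimination_test(graphs, records, "COC(=O)")
    assert np.all(diffs > 0) and p < 0.05
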