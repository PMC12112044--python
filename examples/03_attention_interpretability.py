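"""Collect attention weights and attribute them to substructures.

Trains a compact 2D model on the planted-ester task, then asks the
interpretability framework where the attention mass sits: layer-wise
entropy and effective heads, and mean attention on the ester SMARTS vs
Murcko scaffolds vs BRICS fragments. On a well-trained model the planted
motif should receive visibly more attention than background atoms.
"""

from payloadgnn import (
    ModelConfig,
    MotifTaskSpec,
    TrainConfig,
    attribute_murcko,
    attribute_smarts,
    collect_attention,
    make_variant,
    motif_discrimination_test,
    motif_task_graphs,
    random_split,
    summarize_attention,
    train,
)

graphs, _ = motif_task_graphs(MotifTaskSpec(n_molecules=300, seed=3), embed_3d=False)
parts = random_split(graphs, seed=3).partitions(graphs)
model = make_variant(ModelConfig(variant="smiles_only", hidden_dim=64, seed=3), in_dim=5)
train(model, parts["train"], parts["valid"],
      TrainConfig(learning_rate=1e-3, max_epochs=80, patience=25, seed=3))

positives = [g for g in parts["test"] if g.labels[0] == 1]
records = collect_attention(model, positives)
print(summarize_attention(records).as_frame().to_string(index=False))

for attr in attribute_smarts(positives, records, ["COC(=O)", "C[OH]"]):
    print(f"SMARTS {attr.pattern!r}: matched {attr.n_molecules_matched} molecules, "
          f"mean attention {attr.mean_attention:.3f} ± {attr.std_attention:.3f}")

scaffolds = attribute_murcko(positives, records)
print(f"{len(scaffolds)} distinct Murcko scaffolds in the positive test set")

diffs, p = motif_discrimination_test(positives, records, "COC(=O)")
print(f"motif − background attention: mean {diffs.mean():+.4f} over {len(diffs)} "
      f"molecules, one-sided Wilcoxon p = {p:.2e}")
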