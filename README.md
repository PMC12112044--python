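# payloadgnn

A hybrid graph neural network for molecular bioactivity classification,
built for antibody–drug-conjugate (ADC) payload screening — predicting
whether a small molecule (chiefly a Topoisomerase I inhibitor candidate)
is active, from its 2D structure and optionally its 3D conformer — together
with an attention-based interpretability framework that attributes the
model's focus to chemically meaningful substructures.

## The model

Molecules are heavy-atom graphs with per-atom features (atomic number,
degree, H count, implicit valence, aromaticity, optionally 3D coordinates).
The full architecture is

    MPNN → GAT ×3 (8 heads) → GraphSAGE → mean pool → linear head

with the layer updates

* MPNN:  h_i′ = σ(W h_i + Σ_{j∈N(i)} M(h_i, h_j)),  M an MLP on [h_i ‖ h_j]
* GAT:   e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j]),  α_ij = softmax_j(e_ij),
         h_i′ = σ(Σ_j α_ij W h_j)
* SAGE:  h_i′ = σ(W h_i + (1/|N(i)|) Σ_{j∈N(i)} W h_j)

Ablation variants (`smiles_only`, `no_mpnn`, `no_gat`, `no_sage`) and
five-layer single-architecture baselines (MPNN/GAT/SAGE/GCN) share the
same training and evaluation protocol: molecule-level Bemis–Murcko
scaffold or random 8:1:1 splits, AdamW with early stopping on validation
ROC-AUC, node-budget batching, and an eight-metric report (accuracy,
sensitivity, specificity, MCC, ROC-AUC, F1, balanced accuracy, AUC-PR).
Every attention weight can be collected and attributed to SMARTS patterns,
Murcko scaffolds, BRICS fragments and ring systems. Layers, automatic
differentiation and AdamW are implemented directly on NumPy in float64,
which makes runs bit-reproducible on CPU and lets the tests pin layer
outputs against brute-force evaluation of the equations.

A synthetic planted-motif generator provides self-contained study inputs:
positives carry a grafted ester motif (`COC(=O)`), negatives are verified
motif-free, so the label is exactly the presence of a local substructure.
See `docs/methods.md` for the full model account and design choices.

## Worked example

`examples/02_train_and_evaluate.py` generates a 300-molecule planted-ester
task, embeds conformers, scaffold-splits, trains the full 3D variant and
prints:

```
{'train': 242, 'valid': 28, 'test': 30}
stopped after 60 epochs, best validation ROC-AUC 1.000
            accuracy: 0.9667
         sensitivity: 1.0000
         specificity: 0.9375
                 mcc: 0.9354
             auc_roc: 1.0000
                  f1: 0.9655
   balanced_accuracy: 0.9688
              auc_pr: 1.0000
```

The test partition contains only molecules whose Murcko scaffold never
occurs in training, so these numbers measure generalization across ring
systems, not memorization. `examples/03_attention_interpretability.py`
continues with attention analysis; on its trained model it prints, per
attention layer, the pooled-weight entropy and the effective number of
heads, and then

```
SMARTS 'COC(=O)': matched 15 molecules, mean attention 0.416 ± 0.103
motif − background attention: mean +0.1400 over 15 molecules, one-sided Wilcoxon p = 3.05e-05
```

i.e. the atoms of the planted motif receive significantly more incoming
attention than background atoms — the model is looking at the substructure
that actually determines the label.

The same functionality is scriptable from a shell:

```bash
payloadgnn synth motif-task --n 600 --seed 7 --out task.csv
payloadgnn train --data task.csv --variant smiles_only --split scaffold \
    --seed 7 --lr 1e-3 --max-epochs 120 --out run/
payloadgnn interpret --checkpoint run/model.ckpt --data task.csv --out interp/
payloadgnn ablate --data mols.jsonl --out ablation/ --n-runs 3
```

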