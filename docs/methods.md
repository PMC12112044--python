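# Methods

## The model

`payloadgnn` implements a hybrid graph neural network for binary bioactivity
classification of small molecules — the motivating application is activity
prediction for antibody–drug-conjugate (ADC) payloads, chiefly
Topoisomerase I inhibitors, where an IC50 endpoint is binarized at 100 µM
(strictly below the cutoff = active). Molecules are heavy-atom graphs: each
atom carries (atomic number, heavy-atom degree, attached-H count, implicit
valence, aromaticity flag) and, for 3D variants, its centered Cartesian
coordinates as three extra feature columns. Hydrogens never appear as
nodes. Every bond contributes two directed edge entries.

The full architecture is the fixed sequence

    MPNN → GAT ×3 (8 heads) → GraphSAGE → mean pool → linear head

with per-layer updates

* **MPNN**  h_i′ = σ(W h_i + Σ_{j∈N(i)} M(h_i, h_j)), where the message
  function M is a one-hidden-layer MLP on the concatenation [h_i ‖ h_j].
  The pairwise MLP is the most general form consistent with the update's
  signature; there are no bond features in the featurization.
* **GAT**   e_ij = LeakyReLU(aᵀ[W h_i ‖ W h_j]),
  α_ij = softmax_{j∈N(i)∪{i}}(e_ij),  h_i′ = σ(Σ_j α_ij W h_j).
  A self-loop is added transiently inside the attention computation only,
  so every softmax has nonempty support; it is never stored in the graph.
  Heads are concatenated in the first two attention layers and averaged in
  the third (the standard multi-head convention).
* **GraphSAGE**  h_i′ = σ(W h_i + (1/|N(i)|) Σ_{j∈N(i)} W h_j), full
  neighborhood mean with a single shared weight matrix; an empty
  neighborhood contributes the zero vector.

σ is ReLU everywhere except the printed LeakyReLU inside the attention
logit. Readout is global average pooling over each graph's node embeddings
followed by an affine map to per-task logits; inference applies an
elementwise sigmoid with a 0.5 decision threshold.

Ablation variants drop one named stage (`no_mpnn`, `no_gat`, `no_sage`),
`smiles_only` removes the coordinate columns, and the four baselines stack
five copies of one layer type (MPNN/GAT/SAGE/GCN, the GCN using symmetric
degree normalization with self-loops). The three attention layers use
independent parameters.

## Numerical core

No deep-learning framework is used: layers, a reverse-mode autodiff engine
(`autodiff.py`) and AdamW are implemented directly on NumPy in float64.
This keeps every layer's forward pass byte-deterministic on CPU and lets
the test suite compare outputs against literal per-node brute-force
evaluation of the update equations at 1e-10 tolerances, and gradients
against central finite differences. The softmax is computed with a
per-neighborhood max shift; the shift is attention-invariant, so it is
treated as a constant in the backward pass. Binary cross-entropy is a
single fused primitive stable in the logits.

Defaults that the update equations do not fix: hidden width 64, message-MLP
width 64, Glorot-uniform initialization seeded per model, dropout 0 (fully
reproducible runs), bias vectors initialized at zero. All are `ModelConfig`
fields.

## Training protocol

Splits are 8:1:1 (train/valid/test) at the *molecule* level; multiple 3D
records (conformers, docking poses) of one molecule always share a
partition, and at evaluation a molecule's score is the mean over its
records — splitting by record would leak near-identical geometries across
partitions. The scaffold strategy groups molecules by Bemis–Murcko
scaffold, orders groups by (size descending, scaffold string ascending) and
fills the partition with the largest remaining deficit, so no scaffold ever
straddles partitions and the split is deterministic. A set with fewer
scaffold groups than partitions degenerates (everything lands in train)
with a warning rather than an error.

Optimization is AdamW (decoupled weight decay 0.01) at an initial learning
rate of 1e-4 by default, up to 1000 epochs with early stopping at patience
50 on validation ROC-AUC; the parameters returned are those of the best
monitored epoch, never a later one. "Dynamic batch sizing" is realized as a
node-count budget per batch (default 2000 nodes). Masked binary
cross-entropy supports multi-task sets with missing labels: masked entries
contribute exactly zero to value and gradient.

The eight reported metrics are accuracy, sensitivity, specificity, MCC,
ROC-AUC (trapezoidal), F1, balanced accuracy and AUC-PR (step-interpolated
average precision). Ranking metrics on a single-class partition are
reported as NaN (undefined), never as 0.

## Conformers

3D coordinates come either from user-supplied SDF records or from ETKDG
embedding with MMFF94 minimization (seeded, deterministic). Conformer
deduplication keeps a conformer iff its optimal-superposition (Kabsch)
RMSD to every already-kept conformer exceeds 1.5 Å, scanning greedily in
input order — greedy selection is deterministic and order-preserving.
Coordinates are centroid-centered on storage; orientation is deliberately
not canonicalized, since the architecture consumes raw pose coordinates as
plain features (no distance-based edge reweighting, no equivariance).

## Attention interpretability

Every GAT layer's attention weights are emitted as
(molecule, layer, head, edge) records, self-edges included. Layer
summaries report:

* **entropy** (natural log) of the layer's weights pooled over molecules,
  heads and edges, renormalized to a probability distribution — raw-weight
  mean and std are reported alongside;
* **head importance** — each head's share of *neighbor-directed* attention
  mass. The naive choice, share of total mass, is identically uniform
  (every head's softmax rows each sum to one), so it carries no signal;
  excluding self-edges measures how strongly a head looks beyond the focal
  atom and genuinely differs between heads. Single-atom graphs, which have
  only self-edges, fall back to total mass;
* **effective heads** — the perplexity exp(H) of the head-importance
  distribution, bounded by [1, n_heads] with the extremes attained exactly
  at one-hot and uniform importance;
* **diversity** — the variance of head importance.

The per-atom attention score is the mean incoming edge weight at the final
attention layer, averaged over heads. Attribution aggregates that score
over matched atom sets: SMARTS patterns (e.g. the ester `COC(=O)` and
hydroxyl `C[OH]`), Bemis–Murcko scaffold atoms (one entry per distinct
scaffold; acyclic molecules have the empty scaffold), BRICS fragments
(molecules without BRICS bonds are a single fragment), and fixed-size SSSR
rings (default five-membered). With attention forced uniform every
attribution's mean is identical by construction — the neutrality property
the tests assert.

## The synthetic planted-motif task

The generator emulates a curated single-target bioactivity set at desk
scale. Each molecule is a backbone drawn from a ring-diverse pool (benzene,
pyridine, naphthalene, furan, thiophene, pyrrole, saturated carbo- and
heterocycles, quinoline, plus a few alkyl chains) with 0–2 random
decorations (methyl, hydroxyl, amino, fluoro, ethyl, nitrile, amide,
isopropyl). Positives additionally receive the ester motif grafted at a
random H-bearing atom through its carbonyl carbon (R–C(=O)–O–CH3, matching
`COC(=O)`); negatives are verified to contain zero motif matches, with
bounded resampling. Labels equal motif presence XOR seeded noise flips.
Emitted SMILES are canonical, valid and pairwise distinct; generation is
deterministic per seed, and label-noise flips are drawn from a separate
seeded stream so the molecule set is identical across noise levels (the
noise-monotonicity property is a paired comparison). The ring-diverse pool
exists so Murcko scaffold splits have many groups to distribute — with one
or two scaffolds an 8:1:1 scaffold split is impossible — and every
heteroatom appears in several distinct scaffold groups: an element unique
to one group would be held out of training wholesale by a scaffold split,
and no model can extrapolate to an atom type it has never seen.

Generated conformers are centroid-centered and rotated into a
deterministic principal-axis frame (variance-ordered axes, signs fixed by
coordinate skewness, right-handed third axis). Embedding engines return an
arbitrary orientation per molecule, which the architecture — coordinates
as plain features, no equivariance — would see as pure noise; pose data in
a shared binding-pocket frame, which this emulates, carries a common
orientation structure instead.

What the task does *not* emulate: docking-pose geometry, binding-energy
distributions, activity cliffs, assay noise structure, or the size and
flexibility of real payload molecules (camptothecin-class inhibitors are
much larger). Passing the planted-motif study therefore demonstrates that
the architecture, training loop and attribution pipeline are correct and
that attention concentrates on a genuinely label-determining substructure;
it does not certify real-data accuracy.

## Scaled-down study sizes

The package's experiments run on one CPU: the reference study uses 600
molecules, hidden width 64, learning rate 1e-3 (a short-budget rate chosen
for the compact synthetic task; the 1e-4 default suits long schedules), at
most 200 epochs with patience 50, scaffold split 8:1:1. The 3-seed
ablation uses the same task and splits with at most 150 epochs and
patience 30 per run — enough for the deeper hybrid to converge; a shorter
budget systematically underrates the full model relative to the
faster-converging five-layer baselines and invalidates the comparison.
With these sizes the end-to-end study takes a few minutes.

## Known limitations

* Attention weights are an interpretability heuristic, not a causal
  attribution; the planted-motif discrimination test is a statistical,
  not per-molecule, guarantee.
* The entropy scale of pooled attention grows with the number of pooled
  weights (ln of the support size), so absolute entropies are comparable
  only within a fixed evaluation set.
* Training is dense CPU linear algebra; it is comfortable at thousands of
  molecules but not intended for million-molecule campaigns.
* Conformer *generation* is a convenience; the tested surface consumes
  supplied coordinates.
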