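"""Dataset-preparation rules: IC50 binarization and conformer pruning.

Shows the 100 µM activity cutoff, ETKDG+MMFF94 conformer embedding, and
greedy RMSD-based deduplication at the 1.5 Å cutoff.
"""

import numpy as np

from payloadgnn import ConformerSet, embed_coords, label_from_ic50, prune_conformers

for ic50 in (0.5, 50.0, 100.0, 250.0):
    print(f"IC50 {ic50:>6.1f} µM → label {label_from_ic50(ic50)}")

sets, failures = embed_coords(["CCOC(=O)c1ccccc1"], seed=11, n_conformers=8)
conf = sets[0]
print(f"\nembedded {len(conf)} conformers of {conf.mol_id} "
      f"(energies kcal/mol: {[f'{e:.1f}' for _, e in conf.conformers]})")

pruned = prune_conformers(conf, rmsd_cutoff_A=1.5)
print(f"after 1.5 Å RMSD dedup: {len(pruned)} kept")
again = prune_conformers(pruned, rmsd_cutoff_A=1.5)
assert len(again) == len(pruned), "pruning must be idempotent"
print("pruning its own output changes nothing (idempotent)")
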