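"""Frozen per-atom perception of a 50-SMILES panel, computed with
OpenBabel (pybel) independently of the implementation toolkit.

Each row: (atomic number, heavy-atom degree, total H count,
implicit H count, aromatic flag), indexed in canonical atom order.
"""

OPENBABEL_PANEL = {
    'CCO': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (8, 1, 1, 1, 0)],
    'COC(C)=O': [(6, 1, 3, 3, 0), (8, 2, 0, 0, 0), (6, 3, 0, 0, 0), (6, 1, 3, 3, 0), (8, 1, 0, 0, 0)],
    'c1ccccc1': [(6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'c1ccncc1': [(6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (7, 2, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'CC(C)C': [(6, 1, 3, 3, 0), (6, 3, 1, 1, 0), (6, 1, 3, 3, 0), (6, 1, 3, 3, 0)],
    'CCCCCC': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 1, 3, 3, 0)],
    'CC(N)=O': [(6, 1, 3, 3, 0), (6, 3, 0, 0, 0), (7, 1, 2, 2, 0), (8, 1, 0, 0, 0)],
    'C1CCCCC1': [(6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0)],
    'C1CCOC1': [(6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (8, 2, 0, 0, 0), (6, 2, 2, 2, 0)],
    'c1ccsc1': [(6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (16, 2, 0, 0, 1), (6, 2, 1, 1, 1)],
    'c1ccoc1': [(6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (8, 2, 0, 0, 1), (6, 2, 1, 1, 1)],
    'CCC(C)O': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (6, 3, 1, 1, 0), (6, 1, 3, 3, 0), (8, 1, 1, 1, 0)],
    'CC#N': [(6, 1, 3, 3, 0), (6, 2, 0, 0, 0), (7, 1, 0, 0, 0)],
    'CCN': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (7, 1, 2, 2, 0)],
    'CCOCC': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (8, 2, 0, 0, 0), (6, 2, 2, 2, 0), (6, 1, 3, 3, 0)],
    'CC(=O)O': [(6, 1, 3, 3, 0), (6, 3, 0, 0, 0), (8, 1, 0, 0, 0), (8, 1, 1, 1, 0)],
    'c1ccc2ccccc2c1': [(6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1)],
    'Cc1ccccc1': [(6, 1, 3, 3, 0), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'OCc1ccccc1': [(8, 1, 1, 1, 0), (6, 2, 2, 2, 0), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'CNC': [(6, 1, 3, 3, 0), (7, 2, 1, 1, 0), (6, 1, 3, 3, 0)],
    'CC(C)(C)C': [(6, 1, 3, 3, 0), (6, 4, 0, 0, 0), (6, 1, 3, 3, 0), (6, 1, 3, 3, 0), (6, 1, 3, 3, 0)],
    'C1CCNCC1': [(6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (7, 2, 1, 1, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0)],
    'CCCl': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (17, 1, 0, 0, 0)],
    'CCF': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (9, 1, 0, 0, 0)],
    'C=CC': [(6, 1, 2, 2, 0), (6, 2, 1, 1, 0), (6, 1, 3, 3, 0)],
    'C#C': [(6, 1, 1, 1, 0), (6, 1, 1, 1, 0)],
    'CCS': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (16, 1, 1, 1, 0)],
    'CSC': [(6, 1, 3, 3, 0), (16, 2, 0, 0, 0), (6, 1, 3, 3, 0)],
    'c1ccc2ncccc2c1': [(6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 3, 0, 0, 1), (7, 2, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1)],
    'CC(=O)c1ccccc1': [(6, 1, 3, 3, 0), (6, 3, 0, 0, 0), (8, 1, 0, 0, 0), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'COc1ccccc1': [(6, 1, 3, 3, 0), (8, 2, 0, 0, 0), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'Nc1ccccc1': [(7, 1, 2, 2, 0), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'Oc1ccccc1': [(8, 1, 1, 1, 0), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'CCOC(=O)CC': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (8, 2, 0, 0, 0), (6, 3, 0, 0, 0), (8, 1, 0, 0, 0), (6, 2, 2, 2, 0), (6, 1, 3, 3, 0)],
    'CN(C)C': [(6, 1, 3, 3, 0), (7, 3, 0, 0, 0), (6, 1, 3, 3, 0), (6, 1, 3, 3, 0)],
    'C1CCOCC1': [(6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (8, 2, 0, 0, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0)],
    'CC1CCCCC1': [(6, 1, 3, 3, 0), (6, 3, 1, 1, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0)],
    'CCC#N': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (6, 2, 0, 0, 0), (7, 1, 0, 0, 0)],
    'OCCO': [(8, 1, 1, 1, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (8, 1, 1, 1, 0)],
    'CC(N)C(=O)O': [(6, 1, 3, 3, 0), (6, 3, 1, 1, 0), (7, 1, 2, 2, 0), (6, 3, 0, 0, 0), (8, 1, 0, 0, 0), (8, 1, 1, 1, 0)],
    'CCC(C)=O': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (6, 3, 0, 0, 0), (6, 1, 3, 3, 0), (8, 1, 0, 0, 0)],
    'CCCBr': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (35, 1, 0, 0, 0)],
    'CNC(C)=O': [(6, 1, 3, 3, 0), (7, 2, 1, 1, 0), (6, 3, 0, 0, 0), (6, 1, 3, 3, 0), (8, 1, 0, 0, 0)],
    'CCCCO': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (8, 1, 1, 1, 0)],
    'CC(C)O': [(6, 1, 3, 3, 0), (6, 3, 1, 1, 0), (6, 1, 3, 3, 0), (8, 1, 1, 1, 0)],
    'C1CC1': [(6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0)],
    'C1CCC1': [(6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0)],
    'CCc1ccccc1': [(6, 1, 3, 3, 0), (6, 2, 2, 2, 0), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
    'NCCO': [(7, 1, 2, 2, 0), (6, 2, 2, 2, 0), (6, 2, 2, 2, 0), (8, 1, 1, 1, 0)],
    'COC(=O)c1ccccc1': [(6, 1, 3, 3, 0), (8, 2, 0, 0, 0), (6, 3, 0, 0, 0), (8, 1, 0, 0, 0), (6, 3, 0, 0, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1), (6, 2, 1, 1, 1)],
}
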