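"""Curated parameters of the barnase-barstar coarse-grained model.

The native-contact table lists the four key residue pairs that drive
barnase-barstar association, with the minimum-distance parameter R_min of
each Go contact taken from the bound crystal pose and a uniform well depth
of 3.0 kcal/mol.  Residue numbers follow the usual barnase (chain A,
110 residues) and barstar (chain B, 89 residues) numbering.
"""

from __future__ import annotations

#: (barnase residue, barstar residue, R_min in Angstrom, epsilon in kcal/mol)
NATIVE_CONTACTS = [
    ("Asp37", "Glu46", 4.96, 3.0),
    ("Arg59", "Asp35", 5.65, 3.0),
    ("His102", "Gly31", 4.82, 3.0),
    ("His102", "Ala36", 5.83, 3.0),
]

#: chain lengths of the CG model (one bead per residue)
N_BARNASE = 110
N_BARSTAR = 89

#: production cavity radius, Angstrom
R_CAVITY = 73.46


def contact_table() -> list[tuple[int, int, float, float]]:
    """Native contacts as 0-based bead-index rows ``(iA, iB, r_min, epsilon)``.

    Bead index = residue number - 1 under one-bead-per-residue mapping.
    """
    rows = []
    for res_a, res_b, r_min, eps in NATIVE_CONTACTS:
        ia = int("".join(c for c in res_a if c.isdigit())) - 1
        ib = int("".join(c for c in res_b if c.isdigit())) - 1
        rows.append((ia, ib, r_min, eps))
    return rows
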