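"""Shared constants: amino-acid alphabet, residue masses, GO roots, COD chemistry.

The canonical amino-acid ordering used for every 20-dimensional vector in
this package is alphabetical by 1-letter code (``AA_ORDER``).  All matrices
and profiles index their columns in this order.
"""

from __future__ import annotations

# Canonical 20 amino acids, alphabetical by 1-letter code.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

# Residues tolerated in input sequences but excluded from composition
# vectors: B (Asx), Z (Glx), U (Sec), X (unknown).  They still count
# toward protein length.
AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("BZUX")

#: Average residue masses in Da (monomer minus water), used for mass-mode
#: amino-acid fractions (g AA / g protein).
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788,
    "C": 103.1388,
    "D": 115.0886,
    "E": 129.1155,
    "F": 147.1766,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "K": 128.1741,
    "L": 113.1594,
    "M": 131.1926,
    "N": 114.1038,
    "P": 97.1167,
    "Q": 128.1307,
    "R": 156.1875,
    "S": 87.0782,
    "T": 101.1051,
    "V": 99.1326,
    "W": 186.2132,
    "Y": 163.1760,
}

#: Essential plus conditionally essential amino acids for humans
#: (1-letter codes, subset of AA_ORDER ordering preserved on use).
ESSENTIAL_AA: tuple[str, ...] = (
    "R", "C", "Q", "G", "H", "I", "L", "K", "M", "F", "P", "T", "W", "Y", "V",
)

# Gene Ontology cellular-component reference roots used to build the
# collapse reference: cellular anatomical entity, protein-containing
# complex, and ribosome.
GO_CELLULAR_ANATOMICAL_ENTITY = "GO:0110165"
GO_PROTEIN_CONTAINING_COMPLEX = "GO:0032991"
GO_RIBOSOME = "GO:0005840"
DEFAULT_GO_ROOTS: tuple[str, str, str] = (
    GO_CELLULAR_ANATOMICAL_ENTITY,
    GO_PROTEIN_CONTAINING_COMPLEX,
    GO_RIBOSOME,
)

# Grams of COD per electron equivalent (eeq); 1 eeq = 8 gCOD.
GCOD_PER_EEQ: float = 8.0

# Nominal integer atomic masses used for theoretical oxygen demand.  The
# COD convention in environmental engineering is stoichiometric, so the
# nominal masses give the textbook factors (e.g. fructose: 192/180).
_ATOMIC_MASS = {"C": 12.0, "H": 1.0, "O": 16.0, "N": 14.0, "S": 32.0}

#: Elemental composition of common substrates/metabolites, as atom counts.
COMPOUND_FORMULA: dict[str, dict[str, int]] = {
    "fructose": {"C": 6, "H": 12, "O": 6},
    "glucose": {"C": 6, "H": 12, "O": 6},
    "methanol": {"C": 1, "H": 4, "O": 1},
    "acetate": {"C": 2, "H": 4, "O": 2},
    "lactate": {"C": 3, "H": 6, "O": 3},
    "ethanol": {"C": 2, "H": 6, "O": 1},
    "glycerol": {"C": 3, "H": 8, "O": 3},
    "formate": {"C": 1, "H": 2, "O": 2},
}


def theoretical_cod_factor(formula: dict[str, int]) -> float:
    """Theoretical oxygen demand of a compound, in gCOD per g compound.

    Balances C_c H_h O_o N_n + x O2 -> c CO2 + (h-3n)/2 H2O + n NH3
    (nitrogen stays reduced, as is standard for COD), giving
    x = c + h/4 - o/2 - 3n/4 mol O2 per mol compound.
    """
    c = formula.get("C", 0)
    h = formula.get("H", 0)
    o = formula.get("O", 0)
    n = formula.get("N", 0)
    mol_o2 = c + h / 4.0 - o / 2.0 - 3.0 * n / 4.0
    mw = sum(_ATOMIC_MASS[el] * cnt for el, cnt in formula.items())
    if mw <= 0:
        raise ValueError("empty formula")
    return 32.0 * mol_o2 / mw


#: Built-in gCOD/g factors for the compounds above.
COD_FACTORS: dict[str, float] = {
    name: theoretical_cod_factor(f) for name, f in COMPOUND_FORMULA.items()
}
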