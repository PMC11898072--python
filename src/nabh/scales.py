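"""Per-residue constants behind the physicochemical featurizer.

Residue class sets follow standard biochemistry usage; "basic" is {K, R}
while "all basic" additionally counts the weakly basic histidine.
Propensity scales are the classic Chou-Fasman helix/sheet/turn preference
parameters; hydropathy is the Kyte-Doolittle scale (imported from
biopython's data tables) and the hydrophobicity index is the Eisenberg
consensus scale. Side-chain pKa values are the EMBOSS set; dipeptide
instability weights (DIWV) are imported from biopython.

The RNA-ligation and redox-potential scales are this package's own
enrichment-style substitutes (documented in the methods note): RNA-binding
interfaces are enriched in R, K, H and M and depleted in D and E, and
redox activity is confined to C, M, W, Y and H. They are stored as data,
not code, so an alternative scale can be dropped in via ScaleConfig.
"""

from __future__ import annotations

from Bio.SeqUtils.ProtParamData import DIWV as _DIWV
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

# ---------------------------------------------------------------------------
# Residue class sets
# ---------------------------------------------------------------------------

CLASS_SETS: dict[str, frozenset[str]] = {
    "acidic": frozenset("DE"),
    "basic": frozenset("KR"),
    "all_basic": frozenset("KRH"),
    "aromatic": frozenset("FWY"),
    "ring": frozenset("FWYHP"),
    "hydroxyl": frozenset("STY"),
    "hbond": frozenset("STYNQDEKRHW"),
    "nonpolar": frozenset("AVLIMFWPG"),
    "helix_breaker": frozenset("PG"),
    "strong_helix_breaker": frozenset("P"),
}

# ---------------------------------------------------------------------------
# Per-residue scales (all 20 residues defined in each)
# ---------------------------------------------------------------------------

# Chou-Fasman conformational preference parameters.
CHOU_FASMAN_HELIX: dict[str, float] = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}

CHOU_FASMAN_SHEET: dict[str, float] = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}

CHOU_FASMAN_TURN: dict[str, float] = {
    "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60,
    "G": 1.56, "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59,
    "M": 0.60, "N": 1.56, "P": 1.52, "Q": 0.98, "R": 0.95,
    "S": 1.43, "T": 0.96, "V": 0.50, "W": 0.96, "Y": 1.14,
}

#: Kyte-Doolittle hydropathy (positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = dict(_KYTE_DOOLITTLE)

#: Eisenberg consensus hydrophobicity.
EISENBERG: dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

#: RNA-interface propensity (enrichment-style substitute scale).
RNA_LIGATION: dict[str, float] = {
    "A": 0.00, "C": 0.05, "D": -0.60, "E": -0.60, "F": 0.10,
    "G": 0.15, "H": 0.70, "I": 0.00, "K": 0.85, "L": 0.00,
    "M": 0.50, "N": 0.10, "P": 0.00, "Q": 0.10, "R": 1.00,
    "S": 0.10, "T": 0.05, "V": 0.00, "W": 0.10, "Y": 0.20,
}

#: Redox propensity: non-zero only for redox-active side chains.
REDOX: dict[str, float] = {
    "A": 0.0, "C": 1.0, "D": 0.0, "E": 0.0, "F": 0.0,
    "G": 0.0, "H": 0.3, "I": 0.0, "K": 0.0, "L": 0.0,
    "M": 0.6, "N": 0.0, "P": 0.0, "Q": 0.0, "R": 0.0,
    "S": 0.0, "T": 0.0, "V": 0.0, "W": 0.5, "Y": 0.7,
}

SCALES: dict[str, dict[str, float]] = {
    "helix_propensity": CHOU_FASMAN_HELIX,
    "sheet_propensity": CHOU_FASMAN_SHEET,
    "turn_propensity": CHOU_FASMAN_TURN,
    "hydropathy": KYTE_DOOLITTLE,
    "hydrophobicity": EISENBERG,
    "rna_ligation": RNA_LIGATION,
    "redox": REDOX,
}

# ---------------------------------------------------------------------------
# Ionization constants (EMBOSS set) and dipeptide instability weights
# ---------------------------------------------------------------------------

#: Side-chain pKa values; H, K, R are basic, C, D, E, Y are acidic.
PKA_SIDE_CHAIN: dict[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.5, "R": 12.5, "Y": 10.1,
}
BASIC_SIDE_CHAINS = frozenset("HKR")
PKA_NTERM = 8.6
PKA_CTERM = 3.6


def dipeptide_instability_weights() -> dict[str, dict[str, float]]:
    """The 400-entry dipeptide instability weight table (Guruprasad DIWV)."""
    return {a: dict(row) for a, row in _DIWV.items()}
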