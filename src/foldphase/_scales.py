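"""Pinned per-residue scales and residue-group definitions.

Every set and scale used by the feature engine lives here as a named,
overridable constant, so a re-analysis with different conventions only
touches this module.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy (raw scale, -4.5..4.5).
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Kyte-Doolittle linearly rescaled onto (0, 1): (KD + 4.5) / 9.
KYTE_DOOLITTLE_01 = {aa: (v + 4.5) / 9.0 for aa, v in KYTE_DOOLITTLE.items()}

#: Polyproline-II helix propensity per residue (experimental host-guest
#: propensities in the Hilser/Creamer lineage; pinned here as the package's
#: PPII scale).
PPII_PROPENSITY = {
    "A": 0.37, "C": 0.25, "D": 0.30, "E": 0.42, "F": 0.30,
    "G": 0.13, "H": 0.20, "I": 0.39, "K": 0.56, "L": 0.24,
    "M": 0.36, "N": 0.27, "P": 1.00, "Q": 0.53, "R": 0.38,
    "S": 0.24, "T": 0.32, "V": 0.39, "W": 0.25, "Y": 0.25,
}

# ---------------------------------------------------------------------------
# Six-category scheme used for sticker-type analysis of unfolded ensembles.
# ---------------------------------------------------------------------------
STICKER_GROUPS = {
    "aliphatic": frozenset("AILMV"),
    "aromatic": frozenset("FWY"),
    "unique": frozenset("CP"),
    "acidic": frozenset("DE"),
    "basic": frozenset("HKR"),
    "polar": frozenset("GNQST"),
}

# ---------------------------------------------------------------------------
# Eight-group scheme for binary patterning z-scores.
# ---------------------------------------------------------------------------
PATTERNING_GROUPS = {
    "pol": frozenset("STNQCH"),
    "hyd": frozenset("ILMV"),
    "pos": frozenset("KR"),
    "neg": frozenset("ED"),
    "aro": frozenset("FWY"),
    "ala": frozenset("A"),
    "pro": frozenset("P"),
    "gly": frozenset("G"),
}

# ---------------------------------------------------------------------------
# Composition-feature residue classes.  These are broader, partially
# overlapping sets (distinct from the six-category sticker scheme above).
# ---------------------------------------------------------------------------
COMPOSITION_CLASSES = {
    "positive": frozenset("RK"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQCHG"),
    "aliphatic": frozenset("AILMV"),
    "aromatic": frozenset("FWY"),
    "charged": frozenset("RKDE"),
    "chain_expanding": frozenset("EDRKP"),
    # TOP-IDP convention: residues that favour disorder.
    "disorder_promoting": frozenset("ARGQSPEK"),
    "RY": frozenset("RY"),
}

KJ_PER_KCAL = 4.184


def kj_to_kcal(x: float) -> float:
    """Convert kJ/mol to kcal/mol."""
    return x / KJ_PER_KCAL
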