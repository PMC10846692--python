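"""Sticker identification from unfolded-state conformational ensembles.

Residues whose transient contacts drive chain collapse and phase
separation ("stickers") are identified by their per-residue mean contact
probability in an unfolded ensemble, benchmarked against a Flory-random-
coil (FRC) reference in which chain-chain and chain-solvent interactions
are counterbalanced.  A residue is a strong sticker when its mean contact
probability exceeds the maximum observed anywhere in the reference.

Contacts use a 5 Angstrom cutoff between per-residue representative
points, excluding nearest and second-nearest sequence neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._scales import STICKER_GROUPS
from .synthetic import ConformEnsemble

__all__ = [
    "ContactProfile",
    "contact_matrix",
    "mean_contact_probability",
    "call_stickers",
    "group_contact_fractions",
    "profile_ensemble",
]

DEFAULT_CUTOFF = 5.0
DEFAULT_EXCLUDE = 2


@dataclass
class ContactProfile:
    """Per-residue contact statistics of a target ensemble vs its reference."""

    sequence: str
    mcp: np.ndarray
    reference_max: float = float("nan")
    sticker_flags: np.ndarray | None = None
    group_fractions: dict[str, float] = field(default_factory=dict)
    expected_fractions: dict[str, float] = field(default_factory=dict)
    predominant_stickers: list[str] = field(default_factory=list)


def contact_matrix(
    conformation: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    exclude_neighbors: int = DEFAULT_EXCLUDE,
) -> np.ndarray:
    """Symmetric binary contact map of one conformation.

    Entry (i, j) is 1 iff |i - j| > exclude_neighbors and the inter-point
    distance is <= cutoff; the diagonal is zero.
    """
    coords = np.asarray(conformation, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("conformation must have shape (n_res, 3)")
    n = len(coords)
    if n < 5:
        raise ValueError("need at least 5 residues")
    d = cdist(coords, coords)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    return ((d <= cutoff) & (sep > exclude_neighbors)).astype(np.int8)


def _eligible_partners(n: int, exclude_neighbors: int) -> np.ndarray:
    """Number of eligible contact partners per residue."""
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    return (sep > exclude_neighbors).sum(axis=1)


def mean_contact_probability(
    ensemble: ConformEnsemble,
    cutoff: float = DEFAULT_CUTOFF,
    exclude_neighbors: int = DEFAULT_EXCLUDE,
) -> np.ndarray:
    """Per-residue mean contact probability over an ensemble.

    The indicator of contact with each eligible partner is averaged
    jointly over conformations and partners (the averaging order does not
    affect the mean).  Values lie in [0, 1].
    """
    confs = ensemble.conformations
    if confs.shape[0] < 1:
        raise ValueError("empty ensemble")
    n = confs.shape[1]
    counts = np.zeros(n)
    for conf in confs:
        counts += contact_matrix(conf, cutoff, exclude_neighbors).sum(axis=1)
    return counts / (confs.shape[0] * _eligible_partners(n, exclude_neighbors))


def call_stickers(
    target: ConformEnsemble,
    reference: ConformEnsemble,
    cutoff: float = DEFAULT_CUTOFF,
    exclude_neighbors: int = DEFAULT_EXCLUDE,
) -> ContactProfile:
    """Flag strong stickers in a target ensemble against an FRC reference.

    A residue is flagged iff its mean contact probability exceeds the
    maximum mean contact probability over all residues of the reference
    ensemble of the same sequence.
    """
    if reference is None:
        raise ValueError(
            "a reference ensemble is required: supply an FRC-style ensemble "
            "or generate one with gen_ensemble(..., reference=True)"
        )
    if target.sequence != reference.sequence:
        raise ValueError("target and reference sequences differ")
    mcp = mean_contact_probability(target, cutoff, exclude_neighbors)
    ref_mcp = mean_contact_probability(reference, cutoff, exclude_neighbors)
    ref_max = float(ref_mcp.max())
    flags = mcp > ref_max
    prof = ContactProfile(
        sequence=target.sequence, mcp=mcp, reference_max=ref_max,
        sticker_flags=flags,
    )
    obs, exp = group_contact_fractions(mcp, target.sequence)
    prof.group_fractions = obs
    prof.expected_fractions = exp
    prof.predominant_stickers = _predominant(obs, exp)
    return prof


def group_contact_fractions(
    mcp: np.ndarray, sequence: str
) -> tuple[dict[str, float], dict[str, float]]:
    """Fraction of total mean contact probability per residue category.

    Categories: aliphatic {A,I,L,M,V}, aromatic {F,W,Y}, unique {C,P},
    acidic {D,E}, basic {H,K,R}, polar {G,N,Q,S,T}.  The expected fraction
    of each category is its residue count divided by the sequence length;
    a category whose observed fraction is high and exceeds its expected
    fraction marks the predominant sticker type.
    """
    mcp = np.asarray(mcp, dtype=float)
    if len(mcp) != len(sequence):
        raise ValueError("mcp length does not match sequence")
    seq = sequence.upper()
    known = set().union(*STICKER_GROUPS.values())
    bad = set(seq) - known
    if bad:
        raise ValueError(f"residues outside the 20-letter alphabet: {sorted(bad)}")
    total = float(mcp.sum())
    if total <= 0:
        raise ValueError("total mean contact probability is zero")
    aa_arr = np.array(list(seq))
    obs, exp = {}, {}
    for name, members in STICKER_GROUPS.items():
        mask = np.isin(aa_arr, list(members))
        obs[name] = float(mcp[mask].sum()) / total
        exp[name] = float(mask.sum()) / len(seq)
    return obs, exp


def _predominant(obs: dict[str, float], exp: dict[str, float]) -> list[str]:
    over = [g for g in obs if obs[g] > exp[g]]
    return sorted(over, key=lambda g: obs[g], reverse=True)


def profile_ensemble(
    target: ConformEnsemble,
    reference: ConformEnsemble,
    cutoff: float = DEFAULT_CUTOFF,
    exclude_neighbors: int = DEFAULT_EXCLUDE,
) -> ContactProfile:
    """Full profile: mcp, sticker flags, and residue-type contact fractions."""
    return call_stickers(target, reference, cutoff, exclude_neighbors)
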