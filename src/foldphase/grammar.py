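"""Sequence-grammar feature engine: patterning, composition, enrichment.

Proteins recruited into unfolded-protein deposits are profiled with 91
sequence features per protein: 36 binary patterning z-scores (one per
unordered pair of eight residue groups, self-pairs included) and 55
composition features (amino-acid and class fractions, charge ratios,
scalar physicochemical descriptors, and patch-coverage fractions).  An
abundance z-score completes a 92-long z-vector per protein.  Feature
distributions of an enriched protein set are compared against the
remaining background with two-sample Kolmogorov-Smirnov tests, recording
the signed log p-value for significant features.

Patterning z-scores follow the NARDINI scheme: a windowed compositional-
asymmetry statistic is z-scored against composition-preserving scrambles
of the same sequence, at window sizes 5 and 6 (averaged).  z > 0 means
the sequence is blockier than its scrambles; z < 0 means better mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint
from scipy import stats

from ._scales import (
    AMINO_ACIDS,
    COMPOSITION_CLASSES,
    KYTE_DOOLITTLE_01,
    PATTERNING_GROUPS,
    PPII_PROPENSITY,
)

__all__ = [
    "PatterningConfig",
    "PatchConfig",
    "patterning_zscores",
    "composition_features",
    "find_patches",
    "reference_zscores",
    "abundance_zscore",
    "ks_feature_enrichment",
    "grammar_feature_table",
    "retained_patch_features",
    "STUDY_RETAINED_PATCHES",
]


@dataclass(frozen=True)
class PatterningConfig:
    n_scrambles: int = 1000
    window_sizes: tuple[int, ...] = (5, 6)
    seed: int = 0
    groups: tuple[tuple[str, frozenset], ...] = tuple(PATTERNING_GROUPS.items())

    def __post_init__(self) -> None:
        if any(g < 2 for g in self.window_sizes):
            raise ValueError("window sizes must be >= 2")

    @property
    def pair_names(self) -> list[str]:
        names = [g for g, _ in self.groups]
        return [f"{a}-{b}" for a, b in combinations_with_replacement(names, 2)]


@dataclass(frozen=True)
class PatchConfig:
    min_occurrences_residue: int = 4
    min_occurrences_rg: int = 2
    max_interruptions: int = 2

    def __post_init__(self) -> None:
        if min(self.min_occurrences_residue, self.min_occurrences_rg) < 1:
            raise ValueError("occurrence minima must be positive")


#: Patch features retained in the study's proteome (no Met or Trp patches).
STUDY_RETAINED_PATCHES = tuple(
    f"patch_{aa}" for aa in AMINO_ACIDS if aa not in "MW"
) + ("patch_RG",)


# ---------------------------------------------------------------------------
# Patterning z-scores
# ---------------------------------------------------------------------------


def _window_fractions(ind: np.ndarray, g: int) -> np.ndarray:
    """Sliding-window mean of indicator rows: (n_rows, L) -> (n_rows, L-g+1)."""
    cs = np.cumsum(ind, axis=1, dtype=float)
    cs = np.concatenate([np.zeros((ind.shape[0], 1)), cs], axis=1)
    return (cs[:, g:] - cs[:, :-g]) / g


def _asymmetry(fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
    """sigma = (f_x - f_y)^2 / (f_x + f_y), zero where both vanish."""
    denom = fx + fy
    with np.errstate(invalid="ignore", divide="ignore"):
        sig = np.where(denom > 0, (fx - fy) ** 2 / np.where(denom > 0, denom, 1), 0.0)
    return sig


def patterning_zscores(
    sequence: str, cfg: PatterningConfig | None = None
) -> pd.Series:
    """36 blockiness z-scores, one per unordered residue-group pair.

    For a group pair (X, Y) the statistic is the variance of the windowed
    compositional asymmetry sigma = (f_X - f_Y)^2/(f_X + f_Y) around its
    sequence-wide value, computed at window sizes 5 and 6 with stride 1.
    Self-pairs measure a group against its complement.  Each statistic is
    z-scored against ``n_scrambles`` composition-preserving scrambles
    drawn with the configured seed; the per-window-size z-scores are
    averaged.  Pairs involving a group absent from the sequence get z = 0,
    as do scramble-invariant sequences.
    """
    cfg = cfg or PatterningConfig()
    seq = sequence.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    L = len(seq)
    if L < max(cfg.window_sizes):
        raise ValueError("sequence shorter than the largest window")

    rng = np.random.default_rng(cfg.seed)
    aa_idx = np.array([AMINO_ACIDS.index(a) for a in seq])
    perms = np.empty((cfg.n_scrambles + 1, L), dtype=np.int8)
    perms[0] = aa_idx
    for r in range(1, cfg.n_scrambles + 1):
        perms[r] = aa_idx[rng.permutation(L)]

    group_names = [g for g, _ in cfg.groups]
    members = {g: m for g, m in cfg.groups}
    # indicator cube per group: (n_rows, L)
    ind = {
        g: np.isin(perms, [AMINO_ACIDS.index(a) for a in m]).astype(float)
        for g, m in members.items()
    }
    present = {g: bool(ind[g][0].sum() > 0) for g in group_names}
    global_frac = {g: float(ind[g][0].mean()) for g in group_names}

    z_by_g: dict[int, dict[str, float]] = {}
    for g in cfg.window_sizes:
        fr = {name: _window_fractions(ind[name], g) for name in group_names}
        zs: dict[str, float] = {}
        for a, b in combinations_with_replacement(group_names, 2):
            name = f"{a}-{b}"
            if not present[a] or (a != b and not present[b]):
                zs[name] = 0.0
                continue
            fx = fr[a]
            if a == b:
                fy = 1.0 - fx
                gfx, gfy = global_frac[a], 1.0 - global_frac[a]
            else:
                fy = fr[b]
                gfx, gfy = global_frac[a], global_frac[b]
            sig_global = _asymmetry(np.array([gfx]), np.array([gfy]))[0]
            sig_win = _asymmetry(fx, fy)
            delta = np.mean((sig_win - sig_global) ** 2, axis=1)
            mu, sd = delta[1:].mean(), delta[1:].std(ddof=0)
            zs[name] = float((delta[0] - mu) / sd) if sd > 0 else 0.0
        z_by_g[g] = zs

    out = {
        name: float(np.mean([z_by_g[g][name] for g in cfg.window_sizes]))
        for name in cfg.pair_names
    }
    return pd.Series(out, name="patterning_z")


# ---------------------------------------------------------------------------
# Patches
# ---------------------------------------------------------------------------


def _occurrences(sequence: str, target: str) -> tuple[list[int], int]:
    """Start positions of target occurrences and the occurrence span."""
    if target == "RG":
        span = 2
        occ = [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "RG"]
    else:
        if len(target) != 1 or target not in AMINO_ACIDS:
            raise ValueError(f"invalid patch target {target!r}")
        span = 1
        occ = [i for i, a in enumerate(sequence) if a == target]
    return occ, span


def find_patches(
    sequence: str, target: str, cfg: PatchConfig | None = None
) -> tuple[list[tuple[int, int]], float]:
    """Locate patches of a residue (or the RG dipeptide) in a sequence.

    A patch is a maximal run of target occurrences in which consecutive
    occurrences are separated by at most ``max_interruptions`` non-target
    residues, containing at least four occurrences of a single residue or
    two of RG.  Returns inclusive residue intervals and the fraction of
    the sequence covered by patches.
    """
    cfg = cfg or PatchConfig()
    seq = sequence.upper()
    occ, span = _occurrences(seq, target)
    min_occ = cfg.min_occurrences_rg if target == "RG" else cfg.min_occurrences_residue

    patches: list[tuple[int, int]] = []
    i = 0
    while i < len(occ):
        j = i
        while (
            j + 1 < len(occ)
            and occ[j + 1] - (occ[j] + span) <= cfg.max_interruptions
        ):
            j += 1
        if j - i + 1 >= min_occ:
            patches.append((occ[i], occ[j] + span - 1))
        i = j + 1
    covered = sum(b - a + 1 for a, b in patches)
    return patches, covered / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# Composition features
# ---------------------------------------------------------------------------


def composition_features(
    sequence: str,
    patch_cfg: PatchConfig | None = None,
    retained_patches: tuple[str, ...] = STUDY_RETAINED_PATCHES,
) -> pd.Series:
    """The 55-value composition feature panel for one sequence.

    20 amino-acid fractions; 9 residue-class fractions (positive,
    negative, polar, aliphatic, aromatic, charged, chain-expanding,
    disorder-promoting, R+Y); the R/K and E/D ratios (reported as the
    numerator count when the denominator residue is absent, keeping the
    value finite for z-scoring); net charge per residue, mean scaled
    Kyte-Doolittle hydrophobicity, isoelectric point, polyproline-II
    propensity, and the count of R+Y residues; plus the patch-coverage
    fractions of the retained patch set (19 under the study's retention).
    """
    patch_cfg = patch_cfg or PatchConfig()
    seq = sequence.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    L = len(seq)
    counts = {aa: seq.count(aa) for aa in AMINO_ACIDS}

    feats: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        feats[f"fraction_{aa}"] = counts[aa] / L
    for cls, members in COMPOSITION_CLASSES.items():
        feats[f"fraction_{cls}"] = sum(counts[a] for a in members) / L
    feats["ratio_RK"] = counts["R"] / counts["K"] if counts["K"] else float(counts["R"])
    feats["ratio_ED"] = counts["E"] / counts["D"] if counts["D"] else float(counts["E"])
    feats["ncpr"] = (counts["R"] + counts["K"] - counts["D"] - counts["E"]) / L
    feats["mean_hydrophobicity"] = sum(KYTE_DOOLITTLE_01[a] for a in seq) / L
    feats["isoelectric_point"] = IsoelectricPoint(seq).pi()
    feats["ppii_propensity"] = sum(PPII_PROPENSITY[a] for a in seq) / L
    feats["count_RY"] = float(counts["R"] + counts["Y"])
    for name in retained_patches:
        target = name.split("_", 1)[1]
        _, cov = find_patches(seq, target, patch_cfg)
        feats[name] = cov
    return pd.Series(feats, name="composition")


# ---------------------------------------------------------------------------
# z-scoring and KS enrichment
# ---------------------------------------------------------------------------


def retained_patch_features(sequences: dict[str, str],
                            patch_cfg: PatchConfig | None = None) -> tuple[str, ...]:
    """Patch features with non-zero coverage anywhere in a reference set.

    Mirrors data-driven patch retention: patch types absent across the
    whole reference proteome are dropped before z-scoring.
    """
    patch_cfg = patch_cfg or PatchConfig()
    all_targets = tuple(f"patch_{aa}" for aa in AMINO_ACIDS) + ("patch_RG",)
    keep = []
    for name in all_targets:
        target = name.split("_", 1)[1]
        for seq in sequences.values():
            if find_patches(seq.upper(), target, patch_cfg)[1] > 0:
                keep.append(name)
                break
    return tuple(keep)


def reference_zscores(
    features: pd.DataFrame, reference_ids: list[str] | pd.Index
) -> pd.DataFrame:
    """z-score every feature column against a reference protein set.

    Zero-variance features are dropped (logged via the returned frame's
    ``attrs['dropped_features']``) rather than producing NaNs.
    """
    ref = features.loc[list(reference_ids)]
    if len(ref) < 2:
        raise ValueError("reference set must contain at least 2 proteins")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    keep = sd > 0
    z = (features.loc[:, keep] - mean[keep]) / sd[keep]
    z.attrs["dropped_features"] = list(features.columns[~keep])
    return z


def abundance_zscore(abundance: pd.DataFrame, protein: str | None = None):
    """Abundance z-score(s) over the full mapped protein set.

    Each protein's abundance is summarised as its mean over all groups and
    replicates; the z-score is taken against the distribution of those
    means across every protein in the table (so it is invariant to
    replicate ordering).  With ``protein`` given, returns that protein's
    scalar z; otherwise the full per-protein Series.
    """
    means = abundance.mean(axis=1)
    sd = float(means.std(ddof=0))
    z = (means - float(means.mean())) / sd if sd > 0 else means * 0.0
    z.name = "abundance_z"
    if protein is not None:
        if protein not in z.index:
            raise KeyError(f"protein {protein!r} not in abundance table")
        return float(z.loc[protein])
    return z


def ks_feature_enrichment(
    set_z: pd.DataFrame,
    background_z: pd.DataFrame,
    alpha: float = 0.05,
    label: str = "",
) -> pd.DataFrame:
    """Two-sample KS comparison of an enriched set against the background.

    Per shared feature, the KS p-value compares the enriched set's z
    distribution with the background's.  Features with p < alpha are
    recorded with a signed log10 p: positive when the set's median exceeds
    the background median (enriched), negative otherwise.
    """
    if set_z.empty or background_z.empty:
        raise ValueError("both sets must be non-empty")
    shared = set_z.index.intersection(background_z.index)
    if len(shared):
        raise ValueError("enriched set and background must be disjoint")
    if len(set_z) == 1:
        import warnings

        warnings.warn("enriched set has a single protein: low KS power")
    rows = []
    for feat in set_z.columns.intersection(background_z.columns):
        a = set_z[feat].to_numpy()
        b = background_z[feat].to_numpy()
        p = float(stats.ks_2samp(a, b).pvalue)
        if p < alpha:
            sign = 1.0 if np.median(a) > np.median(b) else -1.0
            rows.append(
                {
                    "feature": feat,
                    "p": p,
                    "signed_log10_p": sign * -np.log10(p),
                    "comparison": label,
                }
            )
    return pd.DataFrame(rows, columns=["feature", "p", "signed_log10_p", "comparison"])


def grammar_feature_table(
    sequences: dict[str, str],
    patterning_cfg: PatterningConfig | None = None,
    patch_cfg: PatchConfig | None = None,
    retained_patches: tuple[str, ...] = STUDY_RETAINED_PATCHES,
) -> pd.DataFrame:
    """91 sequence features (36 patterning z + 55 composition) per protein."""
    patterning_cfg = patterning_cfg or PatterningConfig()
    patch_cfg = patch_cfg or PatchConfig()
    rows = {}
    for pid, seq in sequences.items():
        pat = patterning_zscores(seq, patterning_cfg)
        comp = composition_features(seq, patch_cfg, retained_patches)
        rows[pid] = pd.concat([pat, comp])
    return pd.DataFrame(rows).T
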