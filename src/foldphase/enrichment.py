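"""Proteomics abundance statistics for deposit compositional profiling.

A TMT-style abundance table (proteins x samples, with a group label and a
replicate index per sample) is normalised by per-sample total abundance,
filtered on a presence rule, mean-filled for single missing replicates,
and screened protein-by-protein with a one-way ANOVA.  Proteins passing
the ANOVA are assigned to enrichment sets by Fisher LSD post hoc pairwise
comparisons (pooled-error t-tests).  A (1 - p) smoothing of replicate
z-scores is provided purely for display.

Presence rule: the default ("relaxed") retains proteins detected in at
least n_replicates - 1 replicates of every group, which makes the
one-missing-replicate mean fill reachable.  The stricter literal reading
(exclude proteins detected in <= 3 replicates in ANY group, i.e. require
full detection everywhere) is selectable with ``presence_rule="literal"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentSets",
    "normalize_and_filter",
    "anova_lsd",
    "replicate_zscores",
    "smooth_zscores",
]

_EPS_VAR = 1e-12


@dataclass
class EnrichmentSets:
    """Per-protein ANOVA/LSD verdicts and enrichment-set labels."""

    anova_p: pd.Series
    lsd_p: pd.DataFrame  # proteins x group pairs
    set_label: pd.Series  # e.g. "8xA+FY" or "" (no clean set)
    significant: pd.Series  # ANOVA p < alpha
    alpha: float = 0.05

    def top_proteins(self, n: int | None = None) -> pd.Index:
        """Significant proteins ranked by ANOVA p, optionally capped."""
        ranked = self.anova_p[self.significant].sort_values().index
        return ranked[:n] if n is not None else ranked


def _check_groups(table: pd.DataFrame) -> list[str]:
    if not isinstance(table.columns, pd.MultiIndex):
        raise ValueError("columns must be a (group, replicate) MultiIndex")
    groups = list(dict.fromkeys(table.columns.get_level_values(0)))
    sizes = [len(table[g].columns) for g in groups]
    if len(groups) < 2 or min(sizes) < 2:
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    return groups


def normalize_and_filter(
    raw: pd.DataFrame, presence_rule: str = "relaxed"
) -> pd.DataFrame:
    """Total-abundance normalisation, presence filter, and mean fill.

    Each sample column is divided by its total abundance (missing values
    excluded from the total).  Proteins are then filtered on detection:
    under the default rule a protein must be detected in at least
    n_rep - 1 replicates of every group; under ``"literal"`` it is
    excluded if detected in <= n_rep - 1 replicates of any group.
    Surviving proteins missing exactly one replicate in a group get that
    value filled with the group mean of the detected replicates.
    All-missing proteins are removed.
    """
    groups = _check_groups(raw)
    norm = raw / raw.sum(axis=0, skipna=True)

    detected = norm.notna()
    keep = pd.Series(True, index=norm.index)
    for g in groups:
        n_rep = len(norm[g].columns)
        n_det = detected[g].sum(axis=1)
        if presence_rule == "relaxed":
            keep &= n_det >= n_rep - 1
        elif presence_rule == "literal":
            keep &= n_det > min(3, n_rep - 1)
        else:
            raise ValueError(f"unknown presence_rule {presence_rule!r}")
    keep &= detected.any(axis=1)
    out = norm[keep].copy()

    for g in groups:
        block = out[g]
        miss_one = block.isna().sum(axis=1) == 1
        if miss_one.any():
            fill = block.mean(axis=1, skipna=True)
            for col in block.columns:
                col_full = (g, col)
                mask = miss_one & out[col_full].isna()
                out.loc[mask, col_full] = fill[mask]
    return out


def _anova_oneway(group_slices: list[np.ndarray]) -> tuple[float, float, int]:
    """One-way ANOVA returning (p, MSE, df_error) with exact-tie handling."""
    k = len(group_slices)
    all_vals = np.concatenate(group_slices)
    n = len(all_vals)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in group_slices)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in group_slices)
    df_b, df_w = k - 1, n - k
    mse = ss_within / df_w
    if mse <= _EPS_VAR:
        # exact ties within groups: any between-group difference is "infinitely"
        # significant, identical means are not
        p = 0.0 if ss_between > _EPS_VAR else 1.0
        return p, max(mse, _EPS_VAR), df_w
    F = (ss_between / df_b) / mse
    return float(stats.f.sf(F, df_b, df_w)), float(mse), df_w


def _lsd_pvalue(a: np.ndarray, b: np.ndarray, mse: float, df: int) -> float:
    """Fisher LSD pairwise p: t-test with the pooled ANOVA error."""
    se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
    if se == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    t = (a.mean() - b.mean()) / se
    return float(2 * stats.t.sf(abs(t), df))


def _enrichment_label(
    means: dict[str, float], lsd: dict[tuple[str, str], float], alpha: float
) -> str:
    """Smallest prefix of mean-ranked groups significantly above the rest."""
    order = sorted(means, key=means.get, reverse=True)
    for cut in range(1, len(order)):
        inside, outside = order[:cut], order[cut:]
        ok = all(
            lsd[tuple(sorted((g, h)))] < alpha and means[g] > means[h]
            for g in inside
            for h in outside
        )
        if ok:
            return "+".join(sorted(inside))
    return ""


def anova_lsd(table: pd.DataFrame, alpha: float = 0.05) -> EnrichmentSets:
    """Per-protein one-way ANOVA with Fisher LSD set assignment.

    Proteins with ANOVA p < alpha are assigned the set of groups in which
    they are significantly higher than every remaining group (pairwise LSD
    at the same alpha).  The result is invariant to protein row order and
    to group relabeling up to label permutation.
    """
    groups = _check_groups(table)
    pair_cols = [f"{a}|{b}" for a, b in combinations(sorted(groups), 2)]
    anova_p = pd.Series(index=table.index, dtype=float)
    lsd_p = pd.DataFrame(index=table.index, columns=pair_cols, dtype=float)
    labels = pd.Series("", index=table.index, dtype=object)

    for prot, row in table.iterrows():
        slices = [row[g].dropna().to_numpy(dtype=float) for g in groups]
        if any(len(s) < 2 for s in slices):
            anova_p.loc[prot] = np.nan
            continue
        p, mse, df = _anova_oneway(slices)
        anova_p.loc[prot] = p
        means = {g: s.mean() for g, s in zip(groups, slices)}
        lsd = {}
        for a, b in combinations(sorted(groups), 2):
            ia, ib = groups.index(a), groups.index(b)
            lsd[(a, b)] = _lsd_pvalue(slices[ia], slices[ib], mse, df)
            lsd_p.loc[prot, f"{a}|{b}"] = lsd[(a, b)]
        if p < alpha:
            labels.loc[prot] = _enrichment_label(means, lsd, alpha)

    return EnrichmentSets(
        anova_p=anova_p,
        lsd_p=lsd_p,
        set_label=labels,
        significant=anova_p < alpha,
        alpha=alpha,
    )


def replicate_zscores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-scores of each sample against all samples of the protein."""
    mean = table.mean(axis=1)
    sd = table.std(axis=1, ddof=0).replace(0, np.nan)
    return table.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)


def smooth_zscores(z: pd.DataFrame) -> pd.DataFrame:
    """Display smoothing: mean replicate z scaled by (1 - p) per cell.

    For each protein x group cell, the replicate z-scores are reduced to
    mean(z) x (1 - p) where p is the one-sample t-test p-value of the
    replicates against 0.  A single-replicate group has no defined p and
    is passed through unscaled (with a warning).  The output is a display
    transform only and must never feed back into statistics.
    """
    if not isinstance(z.columns, pd.MultiIndex):
        raise ValueError("columns must be a (group, replicate) MultiIndex")
    groups = list(dict.fromkeys(z.columns.get_level_values(0)))
    out = pd.DataFrame(index=z.index, columns=groups, dtype=float)
    for g in groups:
        block = z[g].to_numpy(dtype=float)
        mean = block.mean(axis=1)
        if block.shape[1] < 2:
            warnings.warn(f"group {g!r} has one replicate: passing mean through")
            out[g] = mean
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat, p = stats.ttest_1samp(block, 0.0, axis=1)
        p = np.where(np.isnan(p), 1.0, p)
        out[g] = mean * (1.0 - p)
    return out
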