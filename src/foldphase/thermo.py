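"""Two-state unfolding thermodynamics and the polyphasic-linkage c* fit.

A globular protein partitions between folded and unfolded states according
to its standard free energy of unfolding dG_U.  Phase separation is assumed
to be driven by the unfolded species alone, occurring at a critical
unfolded concentration c*, so the apparent saturation concentration of the
total protein pool obeys

    c_sat = c* / p_U(dG_U + dG_S),

where p_U is the logistic (Boltzmann two-state) fraction unfolded and dG_S
is a constant cellular stability offset that accounts for proteins being
less stable in cells than dilute-solution measurements suggest.

This module fits (c*, dG_S) to measured (dG_U, c_sat) pairs, and provides
the hydropathy-blob weighting and bootstrap used to put a confidence
envelope on the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from ._scales import KYTE_DOOLITTLE_01

__all__ = [
    "ThermoConfig",
    "ThermoFit",
    "BlobProfile",
    "fraction_unfolded",
    "predict_csat",
    "fit_cstar_shift",
    "detect_blobs",
    "blob_change",
    "cstar_confidence_interval",
]


@dataclass(frozen=True)
class ThermoConfig:
    """Physical constants for the two-state model.

    R is in J/(mol K); free energies passed to this module are in kJ/mol.
    T defaults to 293 K (room-temperature imaging conditions).
    """

    R: float = 8.314
    T: float = 293.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")

    @property
    def RT_kJ(self) -> float:
        """Thermal energy in kJ/mol."""
        return self.R * self.T / 1000.0


@dataclass
class ThermoFit:
    """Result of the global (c*, dG_S) fit."""

    c_star: float
    dG_shift: float
    c_star_sd: float = float("nan")
    dG_shift_sd: float = float("nan")
    r2: float = float("nan")
    n_variants: int = 0


@dataclass
class BlobProfile:
    """Hydropathy-blob decomposition of a sequence.

    ``window_scores`` holds the scaled Kyte-Doolittle score (0-1) averaged
    over 3-residue windows; blobs are residue-unit intervals (start, end)
    inclusive, each spanning >= 4 contiguous windows.
    """

    window_scores: np.ndarray
    hydrophobic_blobs: list[tuple[int, int]] = field(default_factory=list)
    hydrophilic_blobs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def hydrophobic_size(self) -> int:
        return sum(b - a + 1 for a, b in self.hydrophobic_blobs)

    @property
    def hydrophilic_size(self) -> int:
        return sum(b - a + 1 for a, b in self.hydrophilic_blobs)


def fraction_unfolded(
    dG: float | np.ndarray,
    cfg: ThermoConfig | None = None,
    shift: float = 0.0,
) -> float | np.ndarray:
    """Equilibrium fraction of unfolded molecules for unfolding free energy dG.

    p_U = exp(-(dG+shift)/RT) / (1 + exp(-(dG+shift)/RT)), evaluated
    overflow-safely via the logistic sigmoid.  dG and shift are in kJ/mol.
    """
    cfg = cfg or ThermoConfig()
    x = -(np.asarray(dG, dtype=float) + shift) / cfg.RT_kJ
    out = expit(x)
    if np.isscalar(dG) or np.ndim(dG) == 0:
        return float(out)
    return out


def predict_csat(
    dG: float | np.ndarray,
    c_star: float,
    shift: float = 0.0,
    cfg: ThermoConfig | None = None,
    cap: float | None = None,
) -> float | np.ndarray:
    """Predicted saturation concentration c_sat = c* / p_U(dG + shift).

    Diverges as p_U -> 0; if ``cap`` is given, values above it are returned
    as +inf to signal "no phase separation at accessible concentrations".
    """
    if c_star <= 0:
        raise ValueError("c_star must be positive")
    pu = fraction_unfolded(dG, cfg, shift)
    csat = c_star / np.asarray(pu, dtype=float)
    if cap is not None:
        csat = np.where(csat > cap, np.inf, csat)
    if np.isscalar(dG) or np.ndim(dG) == 0:
        return float(csat)
    return csat


def _as_arrays(variants: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    df = variants.dropna(subset=["csat_au"])
    dg = df["dG_kJmol"].to_numpy(dtype=float)
    cs = df["csat_au"].to_numpy(dtype=float)
    if np.any(cs <= 0):
        raise ValueError("measured c_sat values must be positive")
    return dg, cs


def fit_cstar_shift(
    variants: pd.DataFrame,
    cfg: ThermoConfig | None = None,
    x0: tuple[float, float] = (10.0, -10.0),
) -> ThermoFit:
    """Fit (c*, dG_S) by nonlinear least squares on log c_sat residuals.

    ``variants`` must carry columns ``dG_kJmol`` and ``csat_au`` (rows with
    missing c_sat, i.e. non-phase-separating variants, are ignored).
    Residuals are taken on log c_sat to stabilise the diverging 1/p_U
    branch; c* is parameterised on the log scale to stay positive.
    """
    cfg = cfg or ThermoConfig()
    dg, cs = _as_arrays(variants)
    if len(dg) < 3:
        raise ValueError("need at least 3 variants with measured c_sat")
    if np.allclose(dg, dg[0]):
        raise ValueError(
            "all dG_U values are equal: c* and dG_S are not separately "
            "identifiable from a single p_U value"
        )
    log_cs = np.log(cs)

    def resid(theta: np.ndarray) -> np.ndarray:
        log_cstar, shift = theta
        pu = fraction_unfolded(dg, cfg, shift)
        return log_cstar - np.log(pu) - log_cs

    sol = least_squares(resid, x0=[np.log(x0[0]), x0[1]], method="lm")
    c_star = float(np.exp(sol.x[0]))
    shift = float(sol.x[1])
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((log_cs - log_cs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ThermoFit(c_star=c_star, dG_shift=shift, r2=r2, n_variants=len(dg))


# ---------------------------------------------------------------------------
# Hydropathy blobs and the weighted bootstrap for the c* confidence interval
# ---------------------------------------------------------------------------

_BLOB_WINDOW = 3
_BLOB_THRESHOLD = 0.37
_MIN_WINDOWS = 4


def detect_blobs(sequence: str) -> BlobProfile:
    """Decompose a sequence into hydrophobic and hydrophilic blobs.

    The scaled (0-1) Kyte-Doolittle score is averaged over 3-residue sliding
    windows (stride 1).  A run of >= 4 contiguous windows with score > 0.37
    is a hydrophobic blob; a run of >= 4 contiguous windows with score
    <= 0.37 is a hydrophilic blob.  Blob intervals are reported in residue
    units, covering every residue touched by a contributing window.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set(KYTE_DOOLITTLE_01)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    n_win = len(sequence) - _BLOB_WINDOW + 1
    if n_win < 1:
        import warnings

        warnings.warn("sequence shorter than one window; empty blob profile")
        return BlobProfile(window_scores=np.empty(0))
    vals = np.array([KYTE_DOOLITTLE_01[aa] for aa in sequence])
    scores = np.convolve(vals, np.ones(_BLOB_WINDOW) / _BLOB_WINDOW, "valid")
    hydro = scores > _BLOB_THRESHOLD

    prof = BlobProfile(window_scores=scores)
    i = 0
    while i < n_win:
        j = i
        while j + 1 < n_win and hydro[j + 1] == hydro[i]:
            j += 1
        if j - i + 1 >= _MIN_WINDOWS:
            interval = (i, j + _BLOB_WINDOW - 1)  # residue units, inclusive
            (prof.hydrophobic_blobs if hydro[i] else prof.hydrophilic_blobs).append(interval)
        i = j + 1
    return prof


def blob_change(variant: BlobProfile, reference: BlobProfile) -> float:
    """Blob rearrangement of a variant relative to a reference sequence.

    Sum of the magnitude of the *decrease* in total hydrophobic blob size
    and the *increase* in total hydrophilic blob size, in residues; moves
    in the opposite directions are not penalised.
    """
    if len(variant.window_scores) != len(reference.window_scores):
        raise ValueError("profiles come from sequences of different length")
    dec_phobic = max(0, reference.hydrophobic_size - variant.hydrophobic_size)
    inc_philic = max(0, variant.hydrophilic_size - reference.hydrophilic_size)
    return float(dec_phobic + inc_philic)


def picking_weights(
    variants: pd.DataFrame,
    reference_sequence: str,
    floor: float = 0.05,
) -> np.ndarray:
    """Per-variant bootstrap picking weight (10 - blob_change)/10, floored.

    Sequences that barely rearrange the reference's hydropathy blobs are
    drawn more often; the floor keeps every variant drawable when
    blob_change >= 10 would give a non-positive weight.
    """
    ref = detect_blobs(reference_sequence)
    w = np.empty(len(variants))
    for k, seq in enumerate(variants["sequence"]):
        w[k] = (10.0 - blob_change(detect_blobs(seq), ref)) / 10.0
    return np.maximum(w, floor)


def cstar_confidence_interval(
    variants: pd.DataFrame,
    cfg: ThermoConfig | None = None,
    seed: int = 0,
    reference_sequence: str | None = None,
    n_trials: int = 1000,
    n_pick: int = 10,
) -> dict:
    """Blob-weighted bootstrap confidence envelope for the (c*, dG_S) fit.

    Each of ``n_trials`` trials draws ``n_pick`` variants (with replacement)
    with probability proportional to their picking weight and refits.  The
    envelope pairs mean(c*)+SD with mean(dG_S)-SD and vice versa, bracketing
    the predicted c_sat curve.
    """
    cfg = cfg or ThermoConfig()
    df = variants.dropna(subset=["csat_au"]).reset_index(drop=True)
    if len(df) < n_pick:
        raise ValueError(f"need at least {n_pick} variants with measured c_sat")
    if reference_sequence is None:
        reference_sequence = df["sequence"].iloc[0]
    w = picking_weights(df, reference_sequence)
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    central = fit_cstar_shift(df, cfg)

    cstars, shifts = [], []
    for _ in range(n_trials):
        idx = rng.choice(len(df), size=n_pick, replace=True, p=p)
        sub = df.iloc[idx]
        try:
            fit = fit_cstar_shift(sub, cfg, x0=(central.c_star, central.dG_shift))
        except ValueError:
            continue  # degenerate draw (all same dG)
        cstars.append(fit.c_star)
        shifts.append(fit.dG_shift)
    cstars = np.asarray(cstars)
    shifts = np.asarray(shifts)
    c_mean, c_sd = float(cstars.mean()), float(cstars.std(ddof=1))
    s_mean, s_sd = float(shifts.mean()), float(shifts.std(ddof=1))
    return {
        "c_star_mean": c_mean,
        "c_star_sd": c_sd,
        "dG_shift_mean": s_mean,
        "dG_shift_sd": s_sd,
        "n_trials_used": int(len(cstars)),
        # the two envelope parameter pairs bracketing c_sat = c*/p_U
        "envelope_upper": (c_mean + c_sd, s_mean - s_sd),
        "envelope_lower": (c_mean - c_sd, s_mean + s_sd),
        "central_fit": central,
    }
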