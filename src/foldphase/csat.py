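"""Saturation-concentration extraction from optoDroplet pixel intensities.

An optoDroplet experiment images each cell before and after blue-light
activation.  Below the saturation concentration the dilute-phase intensity
after activation tracks the total intensity one-to-one; above it, droplets
form and the dilute-phase intensity plateaus at c_sat.  This module turns
per-cell pixel intensity tables into per-cell (I_dil_before, I_dil_after)
summaries via histogram Gaussian fits, prunes outliers with Cook's
distance, and extracts c_sat as the intensity at which a bootstrap-scanned
segmented regression leaves the one-to-one line.

Histograms use Freedman-Diaconis bin widths (min 10 bins): the binning
policy is scale-free and robust for right-skewed intensity data.  Pixel
screening happens in natural-log space; the dilute/dense fits run on raw
intensity histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

__all__ = [
    "CellRecord",
    "CellFit",
    "ExtractionConfig",
    "CsatResult",
    "cells_from_pixel_table",
    "filter_cells",
    "select_uniform_pixels",
    "fit_dilute_dense",
    "remove_outlier_cells",
    "estimate_csat",
    "extract_csat",
]


@dataclass
class CellRecord:
    """Paired pixel intensities of one segmented cell."""

    cell_id: str
    pixels_before: np.ndarray
    pixels_after: np.ndarray
    max_intensity: float

    def __post_init__(self) -> None:
        self.pixels_before = np.asarray(self.pixels_before, dtype=float)
        self.pixels_after = np.asarray(self.pixels_after, dtype=float)
        if self.pixels_before.shape != self.pixels_after.shape:
            raise ValueError(f"{self.cell_id}: unpaired pixel arrays")
        if np.any(self.pixels_before < 0) or np.any(self.pixels_after < 0):
            raise ValueError(f"{self.cell_id}: negative intensities")


@dataclass
class CellFit:
    """Dilute/dense Gaussian summary of one cell."""

    cell_id: str
    I_dil_before: float = float("nan")
    I_dil_after: float = float("nan")
    I_den_after: float | None = None
    r2_after: float = float("nan")
    n_pixels_used: int = 0
    status: str = "kept"  # or "discarded:<reason>"

    @property
    def kept(self) -> bool:
        return self.status == "kept"

    @property
    def deviation(self) -> float:
        return self.I_dil_before - self.I_dil_after


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds of the extraction algorithm (defaults as published)."""

    max_pixel_fraction: float = 0.25
    freq_width_fraction: float = 0.20
    min_bins: int = 5  # exclusive: need data in MORE than this many bins
    min_pixels: int = 100
    r2_min: float = 0.85
    x_1to1: float = 1000.0
    cook_multiplier: float = 5.0
    bootstrap_trials: int = 50
    bootstrap_fraction: float = 0.9
    min_offdiag_cells: int = 3
    min_hist_bins: int = 10
    split_percentiles: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must lie in (0, 1]")
        for name in ("max_pixel_fraction", "freq_width_fraction", "r2_min",
                     "x_1to1", "cook_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CsatResult:
    """Population-level c_sat verdict."""

    phase_separating: bool
    csat_mean: float = float("nan")
    csat_sd: float = float("nan")
    m: float = float("nan")
    per_trial_splitVal: list[float] = field(default_factory=list)
    n_cells_used: int = 0


def cells_from_pixel_table(
    pixels: pd.DataFrame, max_intensity: float
) -> list[CellRecord]:
    """Build CellRecords from a long pixel table (cell_id, pixel_id, ...)."""
    cells = []
    for cid, grp in pixels.groupby("cell_id", sort=True):
        cells.append(
            CellRecord(
                cell_id=str(cid),
                pixels_before=grp["intensity_before"].to_numpy(),
                pixels_after=grp["intensity_after"].to_numpy(),
                max_intensity=max_intensity,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# Histogram helpers
# ---------------------------------------------------------------------------


def _fd_edges(x: np.ndarray, min_bins: int) -> np.ndarray:
    """Freedman-Diaconis bin edges with a floor on the bin count."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.array([lo - 0.5, hi + 0.5])
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2 * iqr / len(x) ** (1 / 3) if iqr > 0 else 0.0
    n_bins = int(np.ceil((hi - lo) / width)) if width > 0 else min_bins
    # the sqrt(n) floor keeps sharply bimodal histograms resolved (FD alone
    # underbins when the IQR straddles a wide empty gap between modes)
    n_bins = max(n_bins, int(np.ceil(np.sqrt(len(x)))), min_bins)
    return np.linspace(lo, hi, n_bins + 1)


def _gauss(x, a, mu, sig):
    return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)


def _gauss2(x, a1, mu1, s1, a2, mu2, s2):
    return _gauss(x, a1, mu1, s1) + _gauss(x, a2, mu2, s2)


def _fit_single_gaussian(x: np.ndarray, min_bins: int) -> tuple[float, float, float, float]:
    """LSQ single-Gaussian fit to the histogram of x.

    Returns (amplitude, mean, sigma, r2).
    """
    edges = _fd_edges(x, min_bins)
    counts, edges = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    p0 = [counts.max(), float(np.mean(x)), max(float(np.std(x)), 1e-6)]
    popt, _ = curve_fit(
        _gauss, centers, counts, p0=p0,
        bounds=([0, centers.min() - 1, 1e-9], [np.inf, centers.max() + 1, np.inf]),
        maxfev=10000,
    )
    pred = _gauss(centers, *popt)
    ss_tot = np.sum((counts - counts.mean()) ** 2)
    r2 = 1 - np.sum((counts - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return float(popt[0]), float(popt[1]), float(popt[2]), float(r2)


# ---------------------------------------------------------------------------
# Per-cell operations
# ---------------------------------------------------------------------------


def filter_cells(
    cells: list[CellRecord], cfg: ExtractionConfig | None = None
) -> tuple[list[CellRecord], dict[str, str]]:
    """Drop cells in which more than 25% of pixels sit at max intensity.

    Returns the surviving cells plus a {cell_id: reason} log of removals.
    """
    cfg = cfg or ExtractionConfig()
    kept, log = [], {}
    for cell in cells:
        frac = float(np.mean(cell.pixels_before >= cell.max_intensity))
        frac_after = float(np.mean(cell.pixels_after >= cell.max_intensity))
        frac = max(frac, frac_after)
        if frac > cfg.max_pixel_fraction:
            log[cell.cell_id] = f"saturated_fraction={frac:.2f}"
        else:
            kept.append(cell)
    return kept, log


def select_uniform_pixels(
    cell: CellRecord, cfg: ExtractionConfig | None = None
) -> np.ndarray:
    """Indices of pixels numerically similar to the cell's mean intensity.

    The before-activation pixel intensities are converted to natural-log
    space and their histogram fit to a single Gaussian; the fitted curve
    supplies the maximum frequency and mean.  Walking outward from the
    mean, the first bin on either side whose observed frequency falls to
    20% of that maximum bounds the retained intensity range.  Pixels
    outside the bounds, and pixels already saturated before activation,
    are excluded.  Returns paired positions valid in both channels.
    """
    cfg = cfg or ExtractionConfig()
    unsat = cell.pixels_before < cell.max_intensity
    logged = np.log(np.clip(cell.pixels_before, 1e-9, None))
    x = logged[unsat]
    if x.size == 0:
        return np.empty(0, dtype=int)
    if np.ptp(x) == 0:  # perfectly uniform cell
        return np.flatnonzero(unsat)
    edges = _fd_edges(x, cfg.min_hist_bins)
    counts, edges = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    try:
        amp, mu, _sig, _r2 = _fit_single_gaussian(x, cfg.min_hist_bins)
    except (RuntimeError, ValueError):
        return np.empty(0, dtype=int)
    thresh = cfg.freq_width_fraction * amp
    mean_bin = int(np.clip(np.searchsorted(edges, mu) - 1, 0, len(counts) - 1))

    lo_edge = edges[0]
    for b in range(mean_bin, -1, -1):
        if counts[b] <= thresh:
            lo_edge = edges[b + 1]  # first low bin excluded
            break
    hi_edge = edges[-1]
    for b in range(mean_bin, len(counts)):
        if counts[b] <= thresh:
            hi_edge = edges[b]
            break
    keep = unsat & (logged >= lo_edge) & (logged <= hi_edge)
    return np.flatnonzero(keep)


def fit_dilute_dense(
    cell: CellRecord,
    pixels: np.ndarray,
    cfg: ExtractionConfig | None = None,
) -> CellFit:
    """Fit the raw before/after histograms of the selected pixels.

    Before-activation: single Gaussian -> I_dil_before.  After-activation:
    two-Gaussian mixture constrained so the dilute mean cannot exceed
    I_dil_before (the dilute phase cannot be more concentrated than the
    whole cell).  Cells with too few pixels/bins, negative fitted means,
    or after-fit R^2 below threshold are discarded with a reason.
    """
    cfg = cfg or ExtractionConfig()
    fit = CellFit(cell_id=cell.cell_id, n_pixels_used=int(len(pixels)))
    if len(pixels) < cfg.min_pixels:
        fit.status = f"discarded:too_few_pixels({len(pixels)})"
        return fit
    before = cell.pixels_before[pixels]
    after = cell.pixels_after[pixels]

    for name, x in (("before", before), ("after", after)):
        edges = _fd_edges(x, cfg.min_hist_bins)
        occupied = int(np.count_nonzero(np.histogram(x, bins=edges)[0]))
        if occupied <= cfg.min_bins:
            fit.status = f"discarded:too_few_bins({name}={occupied})"
            return fit

    try:
        _, mu_b, _, _ = _fit_single_gaussian(before, cfg.min_hist_bins)
    except (RuntimeError, ValueError):
        fit.status = "discarded:fit_failure(before)"
        return fit
    fit.I_dil_before = mu_b

    edges = _fd_edges(after, cfg.min_hist_bins)
    counts, edges = np.histogram(after, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))

    q25, q90 = np.percentile(after, [25, 90])
    sig0 = max(float(np.std(after)) / 2, 1e-6)
    p0 = [counts.max(), min(q25, mu_b), sig0, counts.max() / 4, q90, sig0]
    lower = [0, 0, 1e-9, 0, 0, 1e-9]
    upper = [np.inf, max(mu_b, 1e-9), np.inf, np.inf, centers.max() + 1, np.inf]
    p0 = np.clip(p0, lower, upper)
    mixture = None
    try:
        popt, _ = curve_fit(_gauss2, centers, counts, p0=p0,
                            bounds=(lower, upper), maxfev=20000)
        pred = _gauss2(centers, *popt)
        r2 = 1 - float(np.sum((counts - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
        mixture = (popt, r2)
    except (RuntimeError, ValueError):
        pass

    single = None
    try:
        _, mu_a, _, r2_s = _fit_single_gaussian(after, cfg.min_hist_bins)
        single = (mu_a, r2_s)
    except (RuntimeError, ValueError):
        pass

    if mixture is None and single is None:
        fit.status = "discarded:fit_failure(after)"
        return fit

    # choose between the degenerate (unimodal) and two-component readings by
    # AIC on the histogram residuals, so the mixture is only believed when a
    # genuine dense peak supports its three extra parameters
    n_bins = len(counts)

    def aic(sse: float, k: int) -> float:
        return n_bins * np.log(max(sse, 1e-12) / n_bins) + 2 * k

    use_single = mixture is None
    if not use_single and single is not None:
        sse_m = (1 - mixture[1]) * ss_tot if ss_tot > 0 else 0.0
        sse_s = (1 - single[1]) * ss_tot if ss_tot > 0 else 0.0
        use_single = aic(sse_s, 3) <= aic(sse_m, 6)

    if use_single:
        # one-to-one regime: the after-distribution is effectively unimodal
        fit.I_dil_after = float(min(single[0], mu_b))
        fit.I_den_after = None
        fit.r2_after = single[1]
    else:
        popt, r2 = mixture
        a1, mu1, s1, a2, mu2, s2 = popt
        area1, area2 = a1 * s1, a2 * s2
        vestigial = min(area1, area2) < 0.01 * (area1 + area2)
        resolved = abs(mu2 - mu1) > 2.0 * max(s1, s2)
        if vestigial or not resolved:
            # the two components describe a single band (a dense phase is
            # several-fold brighter): read the band centre, not a sub-peak
            if vestigial:
                mu = mu1 if area1 >= area2 else mu2
            else:
                mu = (area1 * mu1 + area2 * mu2) / (area1 + area2)
            fit.I_dil_after = float(min(mu, mu_b))
            fit.I_den_after = None
        else:
            fit.I_dil_after = float(min(mu1, mu2))
            fit.I_den_after = float(max(mu1, mu2))
        fit.r2_after = r2

    if fit.I_dil_before < 0 or fit.I_dil_after < 0:
        fit.status = "discarded:negative_mean"
    elif fit.r2_after < cfg.r2_min:
        fit.status = f"discarded:low_r2({fit.r2_after:.3f})"
    return fit


def fits_to_frame(fits: list[CellFit]) -> pd.DataFrame:
    """Tabulate kept CellFits."""
    rows = [
        {
            "cell_id": f.cell_id,
            "I_dil_before": f.I_dil_before,
            "I_dil_after": f.I_dil_after,
            "I_den_after": f.I_den_after,
            "r2_after": f.r2_after,
            "n_pixels_used": f.n_pixels_used,
        }
        for f in fits
        if f.kept
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outlier removal and the split-value scan
# ---------------------------------------------------------------------------


def _compute_m(points: pd.DataFrame, cfg: ExtractionConfig) -> float:
    """m = 0.9 * mean(I_dil_before - I_dil_after) over cells beyond x_1to1."""
    dev = points["I_dil_before"] - points["I_dil_after"]
    out = dev[dev > cfg.x_1to1]
    if out.empty:
        return float("nan")
    return 0.9 * float(out.mean())


def _cook_prune(sub: pd.DataFrame, cfg: ExtractionConfig) -> pd.Index:
    """Indices to drop by the Cook's-distance rule on an OLS fit."""
    if len(sub) < 3:
        return pd.Index([])
    X = sm.add_constant(sub["I_dil_before"].to_numpy())
    model = sm.OLS(sub["I_dil_after"].to_numpy(), X).fit()
    cooks = model.get_influence().cooks_distance[0]
    bad = cooks > cfg.cook_multiplier * np.mean(cooks)
    return sub.index[bad]


def remove_outlier_cells(
    points: pd.DataFrame, cfg: ExtractionConfig | None = None
) -> tuple[pd.DataFrame, float]:
    """Three-step outlier pruning of the I_dil_before vs I_dil_after cloud.

    (1) within sliding intensity deciles, drop cells far off the diagonal
    when their neighbours behave one-to-one; (2) Cook's-distance pruning of
    a linear fit to cells slightly off the diagonal (deviation < m);
    (3) the same pruning for cells far off the diagonal (deviation >= m).
    The threshold m is fixed from the input cloud before any step runs.
    Returns the pruned table and m (NaN when no cell exceeds x_1to1).
    """
    cfg = cfg or ExtractionConfig()
    if len(points) < 2:
        raise ValueError("need at least 2 fitted cells")
    pts = points.reset_index(drop=True)
    m = _compute_m(pts, cfg)

    # step 1: off-diagonal cells inside a one-to-one-behaving decile
    dev = pts["I_dil_before"] - pts["I_dil_after"]
    drop: set[int] = set()
    try:
        deciles = pd.qcut(pts["I_dil_before"], 10, labels=False, duplicates="drop")
    except ValueError:
        deciles = pd.Series(np.zeros(len(pts), dtype=int), index=pts.index)
    for _d, idx in pts.groupby(deciles).groups.items():
        d_dev = dev.loc[idx]
        offenders = d_dev.index[d_dev > cfg.x_1to1]
        for i in offenders:
            neighbors = d_dev.drop(i)
            if len(neighbors) and np.mean(neighbors < cfg.x_1to1 / 2) > 0.8:
                drop.add(i)
    pts = pts.drop(index=drop)

    if np.isnan(m):
        return pts.reset_index(drop=True), m

    # steps 2 and 3: Cook's-distance pruning within each deviation regime
    dev = pts["I_dil_before"] - pts["I_dil_after"]
    for sub in (pts[dev < m], pts[dev >= m]):
        pts = pts.drop(index=_cook_prune(sub, cfg))
    return pts.reset_index(drop=True), m


def _split_fit(x: np.ndarray, y: np.ndarray, s: float) -> tuple[float, float]:
    """Objective terms of the two-segment model split at s.

    Cells with I_dil_before < s are assigned to the one-to-one line
    (y = x); cells with I_dil_before >= s are fit by a line constrained to
    cross the one-to-one line at (s, s).  Returns the combined SSE of both
    segments and 1 - R^2 of the piecewise model.
    """
    below = x < s
    xs, ys = x[~below] - s, y[~below] - s
    if len(xs) < 2:
        return np.inf, np.inf
    denom = float(np.sum(xs * xs))
    b = float(np.sum(xs * ys)) / denom if denom > 0 else 0.0
    sse = float(np.sum((ys - b * xs) ** 2) + np.sum((y[below] - x[below]) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    one_minus_r2 = sse / ss_tot if ss_tot > 0 else 0.0
    return sse, one_minus_r2


def _scan_split(x: np.ndarray, y: np.ndarray, cfg: ExtractionConfig) -> float:
    """Scan candidate split values; return the best c_sat for this sample."""
    lo, hi = np.percentile(x, cfg.split_percentiles)
    cands = np.unique(x[(x >= lo) & (x <= hi)])
    if cands.size == 0:
        cands = np.unique(x)
    sse = np.empty(len(cands))
    omr2 = np.empty(len(cands))
    for k, s in enumerate(cands):
        sse[k], omr2[k] = _split_fit(x, y, s)
    ok = np.isfinite(sse) & np.isfinite(omr2)
    if not ok.any():
        return float(cands[0])
    cands, sse, omr2 = cands[ok], sse[ok], omr2[ok]

    def norm(v: np.ndarray) -> np.ndarray:
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    obj = norm(sse) + norm(omr2)
    if np.allclose(obj, obj[0]):
        warnings.warn("degenerate split scan: all candidates tie; taking smallest")
        return float(cands[0])
    return float(cands[np.argmin(obj)])


def estimate_csat(
    points: pd.DataFrame,
    cfg: ExtractionConfig | None = None,
    seed: int = 0,
    m: float | None = None,
) -> CsatResult:
    """Bootstrap estimate of c_sat from outlier-pruned per-cell fits.

    Cells with deviation >= m are off-diagonal; a population with fewer
    than ``min_offdiag_cells`` of them is declared non-phase-separating.
    Otherwise each of 50 bootstrap trials resamples (with replacement)
    0.9 x the off-diagonal cell count from the off-diagonal set together
    with a same-size resample of the one-to-one cells, scans candidate
    split values, and takes the split minimising the min-max-normalised
    sum of SSE and 1-R^2 of the two-segment model pinned to the
    one-to-one diagonal at the split.  The mean and SD over trials are
    reported.  Resampling both regimes lets the bootstrap SD reflect the
    uncertainty contributed by cells near the breakpoint, which a frozen
    one-to-one set cannot express.
    """
    cfg = cfg or ExtractionConfig()
    if points.empty:
        return CsatResult(phase_separating=False, n_cells_used=0)
    if m is None:
        m = _compute_m(points, cfg)
    if np.isnan(m):
        return CsatResult(phase_separating=False, m=m,
                          n_cells_used=len(points))
    dev = points["I_dil_before"] - points["I_dil_after"]
    off = points[dev >= m]
    diag = points[dev < m]
    if len(off) < cfg.min_offdiag_cells:
        return CsatResult(phase_separating=False, m=m, n_cells_used=len(points))

    rng = np.random.default_rng(seed)
    n_draw = max(int(np.floor(cfg.bootstrap_fraction * len(off))), 1)
    x_diag = diag["I_dil_before"].to_numpy()
    y_diag = diag["I_dil_after"].to_numpy()
    x_off = off["I_dil_before"].to_numpy()
    y_off = off["I_dil_after"].to_numpy()

    splits = []
    for _ in range(cfg.bootstrap_trials):
        idx = rng.choice(len(x_off), size=n_draw, replace=True)
        jdx = rng.choice(len(x_diag), size=len(x_diag), replace=True)
        x = np.concatenate([x_diag[jdx], x_off[idx]])
        y = np.concatenate([y_diag[jdx], y_off[idx]])
        splits.append(_scan_split(x, y, cfg))
    splits_arr = np.asarray(splits)
    return CsatResult(
        phase_separating=True,
        csat_mean=float(splits_arr.mean()),
        csat_sd=float(splits_arr.std(ddof=1)),
        m=m,
        per_trial_splitVal=[float(s) for s in splits_arr],
        n_cells_used=int(len(points)),
    )


def extract_csat(
    pixels: pd.DataFrame,
    max_intensity: float,
    cfg: ExtractionConfig | None = None,
    seed: int = 0,
) -> tuple[CsatResult, pd.DataFrame, dict[str, str]]:
    """Run the full extraction on a long pixel table.

    Returns the population verdict, the pruned per-cell fit table, and an
    audit log of per-cell removals.
    """
    cfg = cfg or ExtractionConfig()
    cells = cells_from_pixel_table(pixels, max_intensity)
    cells, log = filter_cells(cells, cfg)
    fits = []
    for cell in cells:
        idx = select_uniform_pixels(cell, cfg)
        fit = fit_dilute_dense(cell, idx, cfg)
        fits.append(fit)
        if not fit.kept:
            log[cell.cell_id] = fit.status
    table = fits_to_frame(fits)
    if len(table) < 2:
        return CsatResult(phase_separating=False, n_cells_used=len(table)), table, log
    pruned, m = remove_outlier_cells(table, cfg)
    result = estimate_csat(pruned, cfg, seed=seed, m=m)
    return result, pruned, log
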