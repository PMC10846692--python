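"""Synthetic-data generators with known ground truth for every pipeline stage.

Four generators emulate the statistical structure of the study's inputs:

* per-cell pixel-intensity tables, as produced by segmenting confocal
  micrographs of an optoDroplet experiment before and after blue-light
  activation;
* variant tables of (dG_U, c_sat) pairs drawn from the critical unfolded
  concentration law c_sat = c*/p_U(dG_U + dG_S);
* coarse-grained unfolded-state conformational ensembles with planted
  sticker residues, and their attraction-free random-coil references;
* synthetic proteomes (FASTA + replicate abundance tables) with planted
  compositional biases and group-wise differential abundances.

All generators take explicit integer seeds and never touch global random
state.  Pixel noise is multiplicative lognormal (micrograph intensities
are positive and right-skewed); the dense-phase pixel fraction is derived
from intensity conservation so the only ground-truth knob for the
extraction stage is the planted c_sat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermo import ThermoConfig, fraction_unfolded

__all__ = [
    "SyntheticCellParams",
    "SyntheticVariantParams",
    "SyntheticEnsembleParams",
    "SyntheticProteomeParams",
    "gen_optodroplet_cells",
    "gen_variant_table",
    "gen_ensemble",
    "gen_proteome_and_abundance",
]

# Background amino-acid frequencies (approximately human proteome averages).
_BACKGROUND_AA = "ACDEFGHIKLMNPQRSTVWY"
_BACKGROUND_FREQ = np.array([
    0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.043, 0.057, 0.100,
    0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.053, 0.060, 0.012, 0.027,
])
_BACKGROUND_FREQ = _BACKGROUND_FREQ / _BACKGROUND_FREQ.sum()


def _lognormal(rng: np.random.Generator, center: float, cv: float, size) -> np.ndarray:
    """Lognormal draws with the requested natural-scale CV, peaked at ``center``.

    The distribution is parameterised by its mode: intensity levels are
    planted where the pixel histogram peaks, which is the location that
    histogram-Gaussian fits estimate.  At cv = 0 the draws are exactly
    ``center``.
    """
    if cv <= 0:
        return np.full(size, center, dtype=float)
    sigma2 = np.log1p(cv**2)
    mu = np.log(center) + sigma2  # mode = exp(mu - sigma^2) = center
    return rng.lognormal(mu, np.sqrt(sigma2), size)


# ---------------------------------------------------------------------------
# optoDroplet pixel tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCellParams:
    """Conditions for a synthetic optoDroplet cell population."""

    n_cells: int = 200
    csat_true: float = 1000.0
    total_intensity_range: tuple[float, float] = (200.0, 3000.0)
    dense_fold: float = 5.0
    pixel_count_per_cell: int = 400
    noise_cv: float = 0.10
    cell_cv: float = 0.10
    max_intensity: float = 65535.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.pixel_count_per_cell <= 0:
            raise ValueError("counts must be positive")
        if self.csat_true <= 0:
            raise ValueError("csat_true must be positive")
        if self.dense_fold <= 1:
            raise ValueError("dense_fold must exceed 1")
        if not 0 < self.noise_cv < 1:
            raise ValueError("noise_cv must lie in (0, 1)")
        if not 0 <= self.cell_cv < 1:
            raise ValueError("cell_cv must lie in [0, 1)")
        lo, hi = self.total_intensity_range
        if not 0 < lo < hi:
            raise ValueError("total_intensity_range must be increasing and positive")


def gen_optodroplet_cells(
    params: SyntheticCellParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-cell pixel intensities before/after light activation.

    Each cell draws a total expression level uniformly from
    ``total_intensity_range``.  Before activation, pixels are unimodal
    lognormal noise around the total.  After activation, cells below the
    planted c_sat are redrawn from the same distribution (one-to-one
    regime); cells above it become a two-component mixture with the dilute
    component centred at c_sat and the dense component at
    ``dense_fold x total``, with the dense pixel fraction solving the
    intensity-conservation equation mean(after) = mean(before).  Pixels are
    clipped at the detector saturation value.

    Returns ``(pixels, truth)``: the pixel table (columns cell_id,
    pixel_id, intensity_before, intensity_after) and a per-cell
    ground-truth table.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.total_intensity_range
    totals = rng.uniform(lo, hi, params.n_cells)
    # cell-to-cell biological variability of the apparent saturation level
    csat_cells = params.csat_true * np.clip(
        1.0 + params.cell_cv * rng.standard_normal(params.n_cells), 0.2, None
    )
    n_pix = params.pixel_count_per_cell

    frames = []
    truth_rows = []
    for c, (total, csat_cell) in enumerate(zip(totals, csat_cells)):
        before = _lognormal(rng, total, params.noise_cv, n_pix)
        if total <= csat_cell:
            after = _lognormal(rng, total, params.noise_cv, n_pix)
            f_dense = 0.0
        else:
            dense_mean = params.dense_fold * total
            f_dense = (total - csat_cell) / (dense_mean - csat_cell)
            is_dense = rng.random(n_pix) < f_dense
            after = np.where(
                is_dense,
                _lognormal(rng, dense_mean, params.noise_cv, n_pix),
                _lognormal(rng, csat_cell, params.noise_cv, n_pix),
            )
        before = np.minimum(before, params.max_intensity)
        after = np.minimum(after, params.max_intensity)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": f"cell{c:04d}",
                    "pixel_id": np.arange(n_pix),
                    "intensity_before": before,
                    "intensity_after": after,
                }
            )
        )
        truth_rows.append(
            {
                "cell_id": f"cell{c:04d}",
                "total_intensity": total,
                "phase_separated": bool(total > csat_cell),
                "dense_fraction": f_dense,
                "csat_true": params.csat_true,
                "csat_cell": csat_cell,
            }
        )
    pixels = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return pixels, truth


# ---------------------------------------------------------------------------
# Variant tables from the c*/p_U law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticVariantParams:
    """Conditions for a synthetic stability-variant series."""

    c_star_true: float = 10.83
    dG_shift_true: float = -12.9
    dG_list: tuple[float, ...] = tuple(np.linspace(-1.0, 19.0, 12).round(2))
    noise_cv: float = 0.0
    seed: int = 0
    sequence_length: int = 110
    n_mutations: int = 3

    def __post_init__(self) -> None:
        if self.c_star_true <= 0:
            raise ValueError("c_star_true must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def gen_variant_table(
    params: SyntheticVariantParams,
    cfg: ThermoConfig | None = None,
) -> pd.DataFrame:
    """Generate a variant table obeying c_sat = c*/p_U(dG + dG_S).

    Multiplicative mean-zero Gaussian noise with coefficient of variation
    ``noise_cv`` perturbs each c_sat.  Each variant also carries a sequence:
    a fixed random parent with ``n_mutations`` point substitutions per
    variant, so the blob-weighted bootstrap has realistic (small)
    per-variant blob changes.  Ground truth is stored in ``DataFrame.attrs``.
    """
    cfg = cfg or ThermoConfig()
    rng = np.random.default_rng(params.seed)
    aas = np.array(list(_BACKGROUND_AA))
    parent = rng.choice(aas, size=params.sequence_length, p=_BACKGROUND_FREQ)

    rows = []
    for k, dg in enumerate(params.dG_list):
        pu = fraction_unfolded(dg, cfg, shift=params.dG_shift_true)
        csat = params.c_star_true / pu
        if params.noise_cv > 0:
            csat *= 1.0 + params.noise_cv * rng.standard_normal()
        seq = parent.copy()
        pos = rng.choice(params.sequence_length, size=params.n_mutations, replace=False)
        seq[pos] = rng.choice(aas, size=params.n_mutations, p=_BACKGROUND_FREQ)
        rows.append(
            {
                "name": f"var{k:02d}",
                "dG_kJmol": float(dg),
                "csat_au": float(csat),
                "sequence": "".join(seq),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["c_star_true"] = params.c_star_true
    df.attrs["dG_shift_true"] = params.dG_shift_true
    df.attrs["parent_sequence"] = "".join(parent)
    return df


# ---------------------------------------------------------------------------
# Coarse-grained unfolded ensembles with planted stickers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticEnsembleParams:
    """Conditions for a bead-per-residue chain ensemble.

    The chain is freely jointed with hard-sphere excluded volume; sticker
    pairs feel a square-well attraction of range equal to the 5 Angstrom
    contact cutoff, so planted stickers acquire elevated contact frequency.
    ``attraction_strength`` is the well depth in units of kT.
    """

    sequence: str = "GSGSGSGSGSGSGSGSGSGSGSGSGSGSGS"
    sticker_positions: frozenset[int] = frozenset()
    attraction_strength: float = 0.0
    n_conformations: int = 200
    bond_length: float = 3.8
    seed: int = 0
    hard_core: float = 3.0
    contact_range: float = 5.0
    sweeps_per_sample: int = 3
    burn_in_sweeps: int = 30

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < 5:
            raise ValueError("sequence must have at least 5 residues")
        if self.n_conformations < 1:
            raise ValueError("n_conformations must be >= 1")
        if any(not 0 <= i < n for i in self.sticker_positions):
            raise ValueError("sticker_positions outside sequence")


@dataclass
class ConformEnsemble:
    """A conformational ensemble: one representative point per residue."""

    sequence: str
    conformations: np.ndarray  # (n_conf, n_res, 3), Angstrom
    label: str = "target"

    def __post_init__(self) -> None:
        self.conformations = np.asarray(self.conformations, dtype=float)
        if self.conformations.ndim != 3 or self.conformations.shape[2] != 3:
            raise ValueError("conformations must have shape (n_conf, n_res, 3)")
        if self.conformations.shape[1] != len(self.sequence):
            raise ValueError("conformation length does not match sequence")
        if not np.all(np.isfinite(self.conformations)):
            raise ValueError("non-finite coordinates")

    @property
    def n_conformations(self) -> int:
        return self.conformations.shape[0]


def _grow_saw(rng: np.random.Generator, n: int, bond: float, core: float,
              max_restarts: int = 2000) -> np.ndarray:
    """Grow one self-avoiding freely-jointed chain by trial placement."""
    core2 = core * core
    for _ in range(max_restarts):
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(60):
                v = rng.standard_normal(3)
                v *= bond / np.linalg.norm(v)
                cand = coords[i - 1] + v
                d2 = np.sum((coords[: max(i - 1, 0)] - cand) ** 2, axis=1)
                if i < 2 or np.all(d2 >= core2):
                    coords[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise RuntimeError("failed to grow a self-avoiding chain")


def _pair_energy(coords: np.ndarray, sticker_idx: np.ndarray, eps: float,
                 rng_cut: float, core: float) -> float:
    """Square-well energy between sticker pairs (|i-j| > 2), kT units."""
    if eps == 0.0 or len(sticker_idx) < 2:
        return 0.0
    pts = coords[sticker_idx]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    sep = np.abs(sticker_idx[:, None] - sticker_idx[None, :])
    mask = (sep > 2) & (d <= rng_cut)
    return -eps * 0.5 * float(mask.sum())


def _clash(coords: np.ndarray, core: float) -> bool:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu = np.triu_indices(len(coords), k=2)
    return bool(np.any(d[iu] < core))


def gen_ensemble(
    params: SyntheticEnsembleParams, reference: bool = False
) -> ConformEnsemble:
    """Sample a bead-per-residue ensemble, or its attraction-free reference.

    With ``reference=True`` (or zero attraction) conformations are
    independent self-avoiding random chains — the stand-in for a Flory
    random coil in which chain-chain and chain-solvent interactions are
    counterbalanced.  Otherwise a Metropolis pivot-move sampler applies the
    sticker square-well potential, decorrelating between samples with
    ``sweeps_per_sample`` pivot sweeps.
    """
    rng = np.random.default_rng(params.seed)
    n = len(params.sequence)
    label = "reference" if reference else "target"
    eps = 0.0 if reference else params.attraction_strength

    if eps == 0.0:
        confs = np.stack(
            [_grow_saw(rng, n, params.bond_length, params.hard_core)
             for _ in range(params.n_conformations)]
        )
        return ConformEnsemble(params.sequence, confs, label)

    sticker_idx = np.array(sorted(params.sticker_positions), dtype=int)
    coords = _grow_saw(rng, n, params.bond_length, params.hard_core)
    energy = _pair_energy(coords, sticker_idx, eps, params.contact_range,
                          params.hard_core)

    n_accept = 0
    n_tried = 0

    def sweep(coords: np.ndarray, energy: float) -> tuple[np.ndarray, float]:
        nonlocal n_accept, n_tried
        for _ in range(n):
            pivot = rng.integers(1, n - 1)
            # random rotation about the pivot bead applied to the tail
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            theta = rng.uniform(0, 2 * np.pi)
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            Rm = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
            cand = coords.copy()
            cand[pivot:] = (cand[pivot:] - cand[pivot]) @ Rm.T + cand[pivot]
            n_tried += 1
            if _clash(cand, params.hard_core):
                continue
            e_new = _pair_energy(cand, sticker_idx, eps, params.contact_range,
                                 params.hard_core)
            if e_new <= energy or rng.random() < np.exp(energy - e_new):
                coords, energy = cand, e_new
                n_accept += 1
        return coords, energy

    for _ in range(params.burn_in_sweeps):
        coords, energy = sweep(coords, energy)

    confs = np.empty((params.n_conformations, n, 3))
    for k in range(params.n_conformations):
        for _ in range(params.sweeps_per_sample):
            coords, energy = sweep(coords, energy)
        confs[k] = coords

    if n_tried and n_accept / n_tried < 0.02:
        warnings.warn(
            f"pivot acceptance rate {n_accept / n_tried:.3f} < 2%: the "
            "attraction may be too strong for the sampler to decorrelate "
            f"(attraction_strength={eps}, n={n})"
        )
    return ConformEnsemble(params.sequence, confs, label)


# ---------------------------------------------------------------------------
# Synthetic proteomes with planted biases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticProteomeParams:
    """Conditions for a synthetic proteome + abundance experiment."""

    n_proteins: int = 120
    length_range: tuple[int, int] = (60, 200)
    groups: tuple[str, ...] = ("WT", "8xA", "FY", "4Y")
    planted_enriched: dict = field(default_factory=dict)  # group -> set of indices
    planted_bias: dict = field(default_factory=dict)  # e.g. {"fraction_R": 0.10}
    n_replicates: int = 4
    abundance_fold: float = 4.0
    abundance_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.n_proteins < 1:
            raise ValueError("need at least 1 protein")
        all_idx: set[int] = set()
        for g, idx in self.planted_enriched.items():
            if g not in self.groups:
                raise ValueError(f"unknown group {g!r}")
            if all_idx & set(idx):
                raise ValueError("planted_enriched sets must be disjoint")
            all_idx |= set(idx)
            if any(not 0 <= i < self.n_proteins for i in idx):
                raise ValueError("planted index out of range")


def _biased_freq(bias: dict) -> np.ndarray:
    """Shift the background frequencies by additive fraction biases."""
    freq = _BACKGROUND_FREQ.copy()
    for feat, delta in bias.items():
        if not feat.startswith("fraction_"):
            raise ValueError(f"unsupported planted bias {feat!r}")
        aa = feat.split("_", 1)[1]
        if len(aa) != 1 or aa not in _BACKGROUND_AA:
            raise ValueError(f"unsupported planted bias {feat!r}")
        j = _BACKGROUND_AA.index(aa)
        if freq[j] + delta <= 0 or freq[j] + delta >= 1:
            raise ValueError(f"infeasible bias for {feat}: {delta}")
        freq[j] += delta
    return freq / freq.sum()


def gen_proteome_and_abundance(
    params: SyntheticProteomeParams,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic proteome and a TMT-style abundance table.

    Background sequences are drawn i.i.d. from fixed residue frequencies
    (no Met or Trp patches arise unless a bias requests them).  Proteins in
    ``planted_enriched[group]`` have their composition shifted by
    ``planted_bias`` and their abundance multiplied by ``abundance_fold``
    in that group's replicates.  Abundance noise is lognormal with CV
    ``abundance_cv``.

    Returns ``(sequences, abundance, truth)`` where ``abundance`` has a
    (group, replicate) column MultiIndex.
    """
    rng = np.random.default_rng(params.seed)
    aas = np.array(list(_BACKGROUND_AA))
    lo, hi = params.length_range
    planted_all = {i for idx in params.planted_enriched.values() for i in idx}
    biased = _biased_freq(params.planted_bias) if params.planted_bias else _BACKGROUND_FREQ

    sequences: dict[str, str] = {}
    for i in range(params.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        freq = biased if i in planted_all else _BACKGROUND_FREQ
        sequences[f"prot{i:04d}"] = "".join(rng.choice(aas, size=L, p=freq))

    base = rng.lognormal(mean=np.log(100.0), sigma=0.8, size=params.n_proteins)
    cols = pd.MultiIndex.from_tuples(
        [(g, r) for g in params.groups for r in range(1, params.n_replicates + 1)],
        names=["group", "replicate"],
    )
    data = np.empty((params.n_proteins, len(cols)))
    for j, (g, _r) in enumerate(cols):
        mean = base.copy()
        enriched = params.planted_enriched.get(g, set())
        for i in enriched:
            mean[i] *= params.abundance_fold
        data[:, j] = _lognormal(rng, 1.0, params.abundance_cv, params.n_proteins) * mean
    abundance = pd.DataFrame(data, index=list(sequences), columns=cols)

    truth = pd.DataFrame(
        {
            "protein": list(sequences),
            "planted_group": [
                next((g for g, idx in params.planted_enriched.items() if i in idx), "")
                for i in range(params.n_proteins)
            ],
        }
    )
    return sequences, abundance, truth
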