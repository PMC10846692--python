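# foldphase

Quantitative analysis of how the folding stability of globular proteins
controls intracellular phase separation of their unfolded states — and of
the sequence grammar that governs which cellular proteins get recruited
into the resulting unfolded-protein deposits (UPODs).

The package is aimed at quantitative cell biologists and biophysicists
working with optoDroplet-style intracellular phase-separation assays,
unfolded-state conformational ensembles, and TMT proteomics of insoluble
fractions.  It ships synthetic-data generators with known ground truth for
every input, so the whole pipeline is testable without any external
datasets.

## The model

A two-state protein populates its unfolded state with probability

    p_U = exp(−(ΔG°U + ΔG°S)/RT) / (1 + exp(−(ΔG°U + ΔG°S)/RT))

where ΔG°U is the in-vitro standard free energy of unfolding and ΔG°S a
constant offset capturing reduced stability in cells.  If phase separation
is driven by unfolded molecules alone, there is a critical unfolded
concentration c* such that the apparent saturation concentration obeys

    c_sat = c* / p_U        (equivalently  c* = p_U × c_sat).

The pipeline stages are:

1. **c_sat extraction** (`foldphase.csat`) — per-cell before/after-activation
   pixel histograms → Gaussian dilute/dense fits → Cook's-distance outlier
   pruning → bootstrap segmented-regression scan for the intensity at which
   cells leave the one-to-one line.
2. **Thermodynamic linkage fit** (`foldphase.thermo`) — nonlinear fit of
   measured c_sat against c*/p_U(ΔG°U + ΔG°S) in (c*, ΔG°S), with a
   hydropathy-blob-weighted bootstrap confidence envelope.
3. **Sticker identification** (`foldphase.stickers`) — per-residue mean
   contact probability of an unfolded ensemble, sticker calls against a
   Flory-random-coil reference maximum, and residue-type contact fractions.
4. **Sequence grammar** (`foldphase.grammar`) — 36 patterning z-scores
   (blockiness vs composition-preserving scrambles), 55 composition
   features, an abundance z-score, and per-feature two-sample KS enrichment
   of protein sets.
5. **Proteomics statistics** (`foldphase.enrichment`) — total-abundance
   normalisation, presence filtering, one-way ANOVA with Fisher LSD set
   assignment, and (1 − p) z-score smoothing for display.
6. **Synthetic data** (`foldphase.synthetic`) — generators for all of the
   above with planted ground truth.

## Worked example

```python
import foldphase as fp

# a 12-variant stability series obeying c_sat = c*/p_U, 5% noise
variants = fp.gen_variant_table(fp.SyntheticVariantParams(
    c_star_true=10.83, dG_shift_true=-12.9, noise_cv=0.05, seed=11))
fit = fp.fit_cstar_shift(variants)
print(f"c* = {fit.c_star:.2f} a.u., dG_S = {fit.dG_shift:.1f} kJ/mol "
      f"({fp.kj_to_kcal(fit.dG_shift):.1f} kcal/mol), R^2 = {fit.r2:.3f}")

# 200 synthetic optoDroplet cells with a planted c_sat of 1000 a.u.
pixels, truth = fp.gen_optodroplet_cells(
    fp.SyntheticCellParams(n_cells=200, csat_true=1000.0, seed=1))
result, cells, log = fp.extract_csat(pixels, max_intensity=65535.0, seed=7)
print(f"phase separating: {result.phase_separating}, "
      f"c_sat = {result.csat_mean:.0f} +/- {result.csat_sd:.0f} a.u. "
      f"({result.n_cells_used} cells)")
```

prints

```
c* = 10.77 a.u., dG_S = -12.8 kJ/mol (-3.1 kcal/mol), R^2 = 0.996
phase separating: True, c_sat = 1003 +/- 17 a.u. (190 cells)
```

The first line recovers the planted critical unfolded concentration
(10.83 a.u.) and cellular stability offset (−12.9 kJ/mol ≈ −3.1 kcal/mol)
from the noisy variant series; the second recovers the planted saturation
concentration from raw pixel data, with the bootstrap SD covering the truth.

A command-line interface wraps each stage and an end-to-end demo:

```sh
foldphase simulate --seed 5 --out inputs/       # synthetic input bundle
foldphase csat-extract --pixels inputs/cells.csv --out csat.json --seed 5
foldphase thermo-fit --variants inputs/variants.tsv --out thermo.json
foldphase stickers --target inputs/target.xyz --reference inputs/reference.xyz --out stickers.tsv
foldphase enrich --abundance inputs/abundance.tsv --out enrich/
foldphase run-all --seed 5 --out demo/          # everything, with a manifest
```

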