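# Methods

`foldphase` implements a quantitative pipeline connecting the folding
stability of a globular protein to the intracellular phase separation of its
unfolded states, together with the downstream compositional profiling of the
deposits such phase separation produces.  This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic-data tests demonstrate.

## Two-state thermodynamics and polyphasic linkage

A protein with standard free energy of unfolding ΔG°U (kJ/mol) populates its
unfolded state with probability

    p_U = exp(−(ΔG°U + ΔG°S)/RT) / (1 + exp(−(ΔG°U + ΔG°S)/RT)),

an overflow-safe logistic in ΔG°U.  ΔG°S is a constant cellular stability
offset: proteins measured in dilute solution are systematically less stable
in cells, and fusion partners (fluorescent proteins, photo-oligomerising
domains) shift stability further.  Phase separation is assumed to be driven
by unfolded molecules alone, at a critical unfolded concentration c*, so the
apparent saturation concentration of the total pool is

    c_sat = c* / p_U(ΔG°U + ΔG°S).

`fit_cstar_shift` fits (c*, ΔG°S) by nonlinear least squares on **log c_sat**
residuals; the 1/p_U branch diverges for stable variants and log residuals
keep those points from dominating.  c* is parameterised on the log scale to
stay positive.  The fit requires variants spanning more than one ΔG°U value;
a degenerate table raises an error naming the non-identifiability.

* `R` defaults to 8.314 J/(mol·K); a config switch accepts other values
  (e.g. 8.131) for comparison with legacy analyses.  `T` defaults to 293 K.
* At ΔG°U = 13 kJ/mol and 293 K the model gives >99% folded molecules for
  either gas-constant choice.
* kJ→kcal conversion uses 4.184 J/cal.

### Blob-weighted bootstrap for the c* confidence interval

Variant sequences are decomposed into hydropathy blobs: the Kyte–Doolittle
scale mapped linearly onto (0,1) via (KD + 4.5)/9, averaged over 3-residue
windows (stride 1); a run of ≥4 contiguous windows above 0.37 is a
hydrophobic blob, ≥4 windows at or below 0.37 a hydrophilic blob.  Blob
sizes are counted in residues covered by contributing windows.  A variant's
blob change versus the reference is

    max(0, decrease in hydrophobic blob residues)
  + max(0, increase in hydrophilic blob residues),

and its bootstrap picking weight is (10 − blob_change)/10, floored at 0.05
(the formula goes non-positive at blob_change ≥ 10; the floor keeps every
variant drawable).  1000 bootstrap trials each draw 10 variants by weight
(with replacement) and refit; the envelope pairs mean(c*)+SD with
mean(ΔG°S)−SD and vice versa, bracketing the predicted c_sat curve.  Note
that under this scaling serine (0.411) counts as weakly hydrophobic; blob
tests therefore use Q/N/K tracts for genuinely hydrophilic cases.

## Saturation-concentration extraction from optoDroplet pixels

Input: per-cell paired pixel intensities before and after light activation.
Below c_sat the dilute-phase intensity after activation tracks the total
intensity one-to-one; above it, droplets form and the dilute signal plateaus.

Per-cell processing:

1. Cells with >25% saturated pixels are removed (the rule is strictly
   greater-than).
2. Pixels are screened in natural-log space: the before-activation log
   histogram is fit to a single Gaussian; walking out from the fitted mean,
   the first bin on either side whose frequency falls to 20% of the fitted
   maximum bounds the retained range.  Saturated pixels are excluded.  This
   enforces the assumption that pre-activation cells are uniformly bright.
3. Raw-intensity histograms of the retained pixels are fit: a single
   Gaussian before activation (→ I_dil,before) and a two-Gaussian mixture
   after activation with the dilute mean bounded by I_dil,before
   (→ I_dil,after, I_den,after).  Cells with <100 retained pixels, ≤5
   occupied bins, negative fitted means, or after-fit R² < 0.85 are
   discarded with logged reasons.

Histograms use Freedman–Diaconis bin widths with a floor of √n bins
(minimum 10): FD alone underbins sharply bimodal histograms whose IQR
straddles the empty gap between dilute and dense modes.  Mixture fits are
least squares on the histogram (not EM on pixels), initialised from the
25th/90th percentiles.  Two safeguards interpret the mixture: AIC chooses
between the single-Gaussian and mixture readings, and a fitted mixture whose
components are unresolved (separation < 2·max σ) or vestigial (<1% of area)
is treated as one band whose centre is the dilute signal.  Without these, a
skewed unimodal band is split into two overlapping components and the lower
sub-peak mis-read as the dilute phase (≈6% low on synthetic one-to-one
cells).

Outlier pruning on the (I_dil,before, I_dil,after) cloud fixes two
thresholds first: x_1to1 = 1000 a.u. bounds the one-to-one regime, and
m = 0.9·mean(deviation) over cells deviating beyond x_1to1 splits "slightly"
from "largely" off-diagonal.  Then (1) within sliding intensity deciles,
cells deviating beyond x_1to1 while >80% of their decile neighbours deviate
less than x_1to1/2 are dropped (an operationalisation of removing cells off
the diagonal in regimes where neighbours are one-to-one); (2) cells with
deviation < m are fit by OLS and points with Cook's distance above 5× the
mean Cook's distance dropped; (3) the same pruning for deviation ≥ m.
Regressions with fewer than 3 points are skipped and logged.

**Split-value scan.**  A population with fewer than 3 off-diagonal cells is
declared non-phase-separating.  Otherwise 50 bootstrap trials resample, with
replacement, 0.9× the off-diagonal cell count from the off-diagonal set
*and* a same-size resample of the one-to-one cells.  Each trial scans
candidate split values (observed I_dil,before between the 5th and 95th
percentiles) through a two-segment model: cells below the split belong to
the identity line, cells above are fit by a line pinned to cross the
one-to-one line at (split, split).  The split minimising the min–max
normalised sum of the piecewise SSE and 1−R² is the trial's c_sat; the mean
and SD over trials are reported.  Resampling both regimes was a deliberate
choice: with the one-to-one cells frozen, the bootstrap SD collapses toward
zero on well-sampled populations because the cells that actually pin the
breakpoint are never varied, leaving the SD unable to express breakpoint
uncertainty.  Both the two-segment objective and this resampling scheme
were validated by parameter recovery on populations with known planted
c_sat (recovery within ~1–3% with an SD that covers the truth).

## Sticker identification from unfolded-state ensembles

A contact is two residues' representative points within 5 Å, excluding
nearest and second-nearest sequence neighbours.  The per-residue mean
contact probability (mcp) averages the contact indicator jointly over
conformations and eligible partners.  A *strong sticker* is a residue whose
mcp exceeds the maximum mcp anywhere in a Flory-random-coil (FRC) reference
ensemble of the same sequence — an ensemble with chain–chain and
chain–solvent interactions counterbalanced, so the reference maximum sets
the scale of sequence-nonspecific contact.

Representative points are side-chain heavy-atom centroids when full atoms
are supplied (PDB input; CA fallback for glycine) or the single provided
bead (xyz input).  A minimum-heavy-atom-distance convention is not
implemented: this package's ensemble formats reduce to one point per
residue.

Residue types are grouped into six categories — aliphatic {A,I,L,M,V},
aromatic {F,W,Y}, unique {C,P}, acidic {D,E}, basic {H,K,R}, polar
{G,N,Q,S,T} — and each category's fraction of total mcp is compared with
its residue-count fraction; categories observed above expectation, led by
the largest, are the predominant sticker types.

Caveat on the null: comparing two *independent* attraction-free ensembles
flags a spurious residue whenever one run's maximum fluctuates past the
other's — asymptotically a coin flip for the argmax residue.  Spurious
flags are few (<5% of residues pooled over seeds at 120 conformations) but
the "zero flags" guarantee only holds for an ensemble compared against
itself.

## Synthetic data generators

All generators take explicit integer seeds; none touch global random state.

**optoDroplet cells.**  Each cell draws a total expression level uniformly
from `total_intensity_range` (the distribution of expression across cells is
not constrained by any assay; uniform is a deliberate, simple choice and a
free knob).  Pixel noise is multiplicative lognormal, parameterised by its
**mode**: planted intensity levels are where the pixel histogram peaks,
which is the location histogram-Gaussian fits estimate; at noise_cv = 0 the
distributions degenerate to the exact planted values.  Each cell also draws
its own apparent saturation level c_i = c_sat·(1 + cell_cv·ε) — single-cell
heterogeneity of the kind the bootstrap SD is meant to capture.  Cells with
total ≤ c_i redraw the same distribution after activation; cells above it
become a two-component mixture with the dilute component at c_i and the
dense component at dense_fold × total, the dense pixel fraction solving
intensity conservation f·dense + (1−f)·c_i = total exactly.  Pixels are
clipped at the detector maximum.  Defaults: 400 pixels/cell, noise_cv 0.10
(CV of the uniform cytoplasmic pool that survives screening), cell_cv 0.10,
dense_fold 5, totals 200–3000 a.u.

**Variant tables.**  c_sat,i = c*/p_U(ΔG_i + ΔG°S) × (1 + cv·ε) with
mean-zero Gaussian ε.  Sequences are a fixed random parent with a few point
substitutions per variant so the blob-weighted bootstrap sees realistic
(small) blob changes.  Defaults plant c* = 10.83 a.u. and ΔG°S = −12.9
kJ/mol over 12 variants spanning ΔG°U −1 to +19 kJ/mol.

**Ensembles.**  Bead-per-residue freely-jointed chains, bond length 3.8 Å,
hard-sphere excluded volume 3.0 Å between non-bonded beads.  References are
independently grown self-avoiding chains.  Targets add a square-well
attraction of depth `attraction_strength` (kT) and range 5 Å between
planted sticker pairs (|i−j| > 2), sampled by Metropolis pivot moves (30
burn-in sweeps, 3 sweeps between samples; a warning fires if pivot
acceptance drops below 2%).  The planted architecture used in tests — two
aromatic sticker pairs on a 30-mer polar background at 2.5 kT — was chosen
because isolated single stickers never bind detectably (neighbour exclusion
leaves them at most a couple of eligible partners) and stronger wells
collapse the whole chain.  A known feature of this model: residues bridging
the two bound sticker pairs ride along and occasionally show genuinely
elevated contact probability; recovery statistics therefore score spacers
outside the ±2-bond interaction shell.

**Proteomes.**  Background sequences are drawn i.i.d. from human-like
residue frequencies; planted proteins shift the frequency of a chosen
residue additively (e.g. fraction_R +0.10) and multiply their abundance by
`abundance_fold` (default 4) in their group's replicates.  Abundance noise
is lognormal, CV 0.10, four replicates per group.

## Sequence-grammar features

**Patterning (36 z-scores).**  Eight residue groups: pol {S,T,N,Q,C,H},
hyd {I,L,M,V}, pos {K,R}, neg {E,D}, aro {F,W,Y}, ala {A}, pro {P},
gly {G}.  For each unordered pair (X,Y) the blockiness statistic is the
variance of the windowed compositional asymmetry
σ = (f_X − f_Y)²/(f_X + f_Y) around its sequence-wide value, windows of
g = 5 and g = 6 with stride 1; self-pairs score a group against its
complement.  Each statistic is z-scored against 1000 composition-preserving
scrambles (seeded), and the two window sizes' z-scores are averaged.  z > 0
means blockier than scrambles, z < 0 better mixed.  Pairs involving a group
absent from the sequence are defined as z = 0 (scrambling cannot change an
absent group's pattern), as are scramble-invariant sequences.

**Composition (55 features).**  20 amino-acid fractions; 9 class fractions
(positive {R,K}, negative {D,E}, polar {S,T,N,Q,C,H,G}, aliphatic
{A,I,L,M,V}, aromatic {F,W,Y}, charged, chain-expanding {E,D,R,K,P},
disorder-promoting {A,R,G,Q,S,P,E,K} per the TOP-IDP convention, and R+Y);
R/K and E/D ratios (reported as the numerator count when the denominator
residue is absent, keeping z-scores finite); net charge per residue, mean
scaled Kyte–Doolittle hydrophobicity, isoelectric point (biopython's
Henderson–Hasselbalch bisection), polyproline-II propensity (a pinned
experimental per-residue scale), and the R+Y count; plus patch-coverage
fractions.  A patch is a maximal run of ≥4 occurrences of a residue (≥2 of
the RG dipeptide) with ≤2 interrupting residues between consecutive
occurrences; coverage is patch residues over sequence length.  The study
retention keeps 19 patch features (all residues except M and W, plus RG);
`retained_patch_features` recomputes retention data-driven from any
reference set.  All definitional sets live in one module
(`foldphase._scales`) as overridable constants.

**z-scores and enrichment.**  Composition features are z-scored against the
full mapped protein set (zero-variance features dropped, logged).  The
abundance z-score summarises each protein as its mean normalised abundance
over all groups and replicates, z-scored across proteins — yielding 92
z-scores per protein (36 + 55 + 1).  Feature enrichment of a protein set
against the remaining background uses the two-sample Kolmogorov–Smirnov
test per feature; p < 0.05 records a signed log₁₀ p, positive when the
set's median z exceeds the background's.  The KS test is conservative on
heavily tied features (e.g. patch types absent from most proteins); type-I
calibration is assessed on features with effectively continuous
distributions.

## Proteomics enrichment statistics

Columns are normalised by total abundance (each sample sums to 1).  The
presence rule retains proteins detected in ≥ n_rep − 1 replicates of every
group — the reading that makes the subsequent fill rule reachable — and a
single missing replicate in a group is filled with the group mean of the
detected replicates; a stricter literal rule (full detection required) is
selectable.  Each protein is screened by one-way ANOVA; proteins passing at
α = 0.05 are assigned to enrichment sets by Fisher LSD pairwise
comparisons (t-tests on the pooled ANOVA mean-square error, df = N − k):
the set label is the smallest prefix of mean-ranked groups in which the
protein is significantly higher than every remaining group.  Exact
within-group ties use an ε floor on the MSE (identical means → p = 1, any
separation → p = 0).  "Top" proteins are all ANOVA-significant proteins
ranked by p, optionally capped.  For display, replicate z-scores are
reduced per protein × group to mean(z)·(1 − p) with p from a one-sample
t-test against zero — a smoothing transform only, never fed back into
statistics; single-replicate groups pass through unscaled with a warning.

## Problem sizes

Test and acceptance runs use sizes chosen to exercise every code path with
comfortable statistics: 200 cells × 400 pixels for c_sat recovery (plus a
five-point planted sweep at 120 cells), 12-variant tables with 100 noisy
repetitions for the c* fit, 200–750 conformations per ensemble condition
(the acceptance script pools three 250-conformation replicas per side),
70–80-protein null proteomes with 120–150 random-set draws for KS
calibration, and 1000-protein null tables for ANOVA calibration.

## Limitations

* The synthetic micrographs have no segmentation errors, point-spread
  blur, background fluorescence, or spatial pixel correlation; passing
  recovery tests shows the estimator chain is correct and calibrated under
  the stated noise model, not that it is robust to imaging artefacts.
* The chain model is a freely-jointed homopolymer with square-well
  stickers; it validates the contact-probability statistics, not any
  real protein's unfolded-state energetics.
* The breakpoint estimator reads intensities in histogram-peak units; its
  bootstrap SD reflects cell-to-cell variability only through the planted
  cell_cv.
* TMT ratio compression, peptide-level inference, and batch effects are
  not emulated; the ANOVA/LSD calibration holds for well-behaved lognormal
  abundance noise.
* The split-value scan's candidate grid is the set of observed
  intensities, so resolution near the breakpoint is limited by cell
  density there.
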