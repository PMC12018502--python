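# Methods

## Overview

`dfcdtx` implements an imaging-transcriptomics analysis chain for resting-state
fMRI: per-subject **dynamic functional connectivity density (dFCD) variability**
maps, a covariate-adjusted voxelwise two-group contrast with cluster-level
multiple-comparison correction, a **PLS** association between the regional
contrast map and a region × gene expression matrix, and three gene-level
follow-ups (over-representation against GMT collections, cell-type/region
specificity via **pSI**, and PPI hub extraction). Because real patient scans and
the proprietary expression/reference databases are not redistributable, the
package ships a synthetic-data generator that emulates every input with planted,
recoverable ground truth; all tests and the acceptance script run on it.

## dFCD variability

For each subject the BOLD series is restricted to the analysis mask (atlas
nonzero ∩ nonzero temporal variance). Sliding windows of `window_width = 50` TR
advance in steps of `step = 10` TR; a trailing partial window is discarded, so a
230-TR series yields 19 windows. Within a window, the FCD of voxel *v* is the
number of other masked voxels *u* with Pearson r(v, u) strictly greater than
`r_threshold = 0.2`; only positive correlations count by default (negative
correlations after global-signal handling are ambiguous), and zero-variance
voxels have r defined as 0. dFCD variability is the sample SD (n−1) of the
degree across windows.

Numerics: each voxel's windowed series is centred and scaled to unit norm once,
so the voxel × voxel correlation matrix is a Gram product evaluated blockwise
(2048 rows at a time). This bounds memory without changing a single comparison
— the suite asserts exact integer equality with a naive per-pair double loop on
random instances. Degree at the threshold uses strict `>`; a weighted variant
(sum of suprathreshold r) exists behind `FCDParams.weighted` but is not the
default.

**Normalisation.** `FCDParams.normalize=True` z-scores the SD map over the mask
(mean 0, SD 1). This is the display convention for group-mean maps. Group
*inference* in the bundled pipelines runs on the **raw** SD maps: dividing each
subject by their own noisy global SD measurably dilutes a real group contrast,
and nothing in the method requires the rescaling for a linear model with an
intercept. Both modes are exposed.

## Group statistics

Demographics: Pearson χ² without continuity correction for categorical columns
(the printed 26/21 vs 24/22 gender split reproduces χ² = 0.093) and
pooled-variance two-sample t for continuous ones.

Voxelwise model: OLS per masked voxel on [intercept, group (patient = 1),
age, sex], t = group coefficient / SE, df = n − rank(design). With no
covariates this equals the textbook pooled two-sample t (asserted to 1e-10).

Cluster correction: voxels with |t| above the two-tailed `voxel_p = 0.001`
quantile of t(df) are labelled into connected components (26-connectivity by
default; positive and negative excursions labelled separately so opposite-sign
clusters never merge). Two corrected p-values are available:

- **permutation** (default): the group labels are permuted (covariates stay
  attached to their subjects; rank-deficient relabellings — e.g. a draw exactly
  collinear with the sex indicator — are redrawn), the maximum cluster size
  over both signs is recorded per permutation, and a cluster's corrected p is
  the add-one proportion of permutation maxima at least as large. This is the
  max-statistic FWER construction, exactly valid under exchangeability.
- **rft**: a Gaussian-random-field approximation. Smoothness (per-axis FWHM) is
  estimated from the spatial gradients of the normalised residuals, the t
  threshold is converted to an equivalent Gaussian level, and the expected
  number of clusters of the observed size gives the corrected p (expected-
  cluster-count form for a 3D field). This is the classically named method; at
  desk scale the permutation route is the calibrated default.

Clusters with corrected p < `cluster_p = 0.05` are reported with the dominant
atlas region, signed peak t, peak location in world (mm) coordinates via the
affine (ties broken by first voxel in lexicographic order), and size.

## PLS imaging-transcriptomics

The regional response is the mean t over each region's masked voxels (regions
fully removed by masking are dropped, with a log entry; fewer than three
surviving regions is an error). Genes are z-scored across regions, and a
one-component PLS regression (NIPALS-equivalent; verified against an
independently coded NIPALS iteration to 1e-8) yields per-gene component-1
weights. The component sign is fixed so region scores correlate positively with
the response; "PLS+" genes (most positive weights) are then genes whose
expression is higher where the contrast is higher. Signed top-N lists use a
deterministic tie-break by gene symbol; N defaults to 1318 per tail (the
production-scale list size) but is a free parameter — synthetic fixtures use
smaller N. An optional regional bootstrap (resampling regions with replacement,
sign-aligning each refit to the original component) provides Z = weight / SE as
an alternative ranking statistic.

No correction for spatial autocorrelation of the regional maps is applied, and
none is claimed: the generator plants genes by exact correlation with the
target map, so recovery there does not demonstrate robustness to spatially
autocorrelated nulls on real brains.

## Enrichment

One-sided hypergeometric upper-tail p per gene set (P[X ≥ overlap]), BH-FDR q
across the sets of a collection. The background defaults to the tested
universe — all genes in the expression matrix — because the ranking operated on
exactly that universe, not the genome.

## Specificity (pSI)

The specificity index of gene g for type t is rank-based: for each other type
o, genes are ranked by mean-expression ratio t/o (rank 1 = most enriched;
computed as ranks of log-mean differences, which is the same ordering), and SI
is the mean rank across comparisons. pSI is the probability of an SI at least
as small under permutation of the sample type labels. When the number of
distinct label assignments is at most `n_perm`, the permutation distribution is
enumerated exhaustively and the p is exact; otherwise `n_perm` seeded shuffles
are drawn and the add-one estimator is used.

A structural property of this null: for a maximally specific gene the permuted
SI ties the observed one whenever the permutation happens to hand that type the
largest share of the high samples, so pSI is bounded below by roughly the
chance-top-rank probability (~1/n_types at few replicates; 19/84 for 3 types ×
3 samples). Fine thresholds (0.001, 0.0001) therefore only bite on wide
reference panels with many types — which is what real cell-type panels are.
Candidate sets at the nested thresholds 0.05 ⊇ 0.01 ⊇ 0.001 ⊇ 0.0001 are
asserted to nest on every run; list enrichment per type × threshold is a
one-sided Fisher exact test, with p = 1 recorded for empty candidate sets.

## PPI

Edges are kept when both endpoints are in the gene list and the combined
confidence is strictly greater than 0.9; duplicates keep the maximum
confidence, self-loops are dropped, and isolated listed genes remain as
degree-0 nodes. Degree is computed on this induced subgraph (not the full
interactome — a documented choice). Hubs are the top ceil(0.15 · n) nodes by
degree, with all ties at the boundary included and a deterministic secondary
order by symbol.

## Synthetic data: what it emulates and what it does not

**BOLD.** Each of `n_regions = 24` rectangular parcels (tiling a 12 × 12 × 6
grid at 3 mm) carries a latent Markov state (2 states). Parcels are grouped
into 2 fixed communities; voxels of two parcels share a community latent signal
exactly when their states coincide, plus unit i.i.d. noise, giving an aligned
within-window correlation of coupling² / (coupling² + 1) ≈ 0.45 at the default
`coupling = 0.9` — about twice the 0.2 threshold, so partial alignment toggles
connectivity. States are piecewise constant over `state_step = 10` TR blocks
(the sliding step: reconfiguration on the timescale the windows resolve) and
switch with per-step probability 0.08 (controls everywhere, patients outside
affected parcels) vs 0.01 (patients' affected parcels; default affected set =
the whole first community). Rare switching freezes a patient's affected
community, so its windowed degree barely moves across windows; control
communities reconfigure 1–3 times per run, producing the planted reduction in
dFCD variability (~20–25% at the defaults). Equal rates give an exact null.
T = 230 at TR 2 s, 20 subjects per group. Ages/sexes are drawn from identical
distributions in both groups (a `confounded` flag shifts patient age for
covariate-stress tests). Not emulated: hemodynamics/HRF, physiological noise,
head motion, spatial smoothing — so absolute dFCD values and smoothness-
dependent behaviour (e.g. RFT calibration) are not representative of real data,
and passing tests certify the statistical machinery, not scanner realism.

**Expression.** Planted genes are constructed as ρ·z(d) + √(1−ρ²)·e with e
residualised against the target map d and standardised, so their empirical
correlation with d equals ±`link_strength` exactly; null genes are i.i.d.
normal (no spatial autocorrelation, no donor structure).

**Gene sets / profiles / PPI.** One GMT set drawn mostly from planted genes
among random sets; cell-type profiles with a fold-elevated gene module for one
type (lognormal background, no compositional effects); an edge list whose
designated hubs receive ≥ `hub_degree` partners at confidence > 0.9 over mixed-
confidence background edges.

All randomness flows from one integer seed through named substreams (`bold`,
`demographics`, `expression`, `sets`, `ppi`, `profiles`), so stages regenerate
independently and bit-identically.

## Problem sizes and calibration checks

The calibration suite runs the full chain on the 12 × 12 × 6 / 24-region
example grid: 20 null cohorts (equal rates, 12 + 12 subjects, T = 150) for
family-wise error (≤ 3/20 seeds with any significant cluster, the binomial
acceptance region for FWER 0.05) and 20 effect cohorts (0.08 vs 0.01, 20 + 20,
T = 230) for detection of the affected parcels with a negative peak (≥ 18/20),
each with 1000 permutations. PLS recovery uses 60 regions × 2000 genes with 40
planted at ρ = 0.6 (AUC ≥ 0.9). These sizes keep the whole suite around two
minutes on one CPU while leaving each check statistically meaningful.

## Degenerate inputs and tie-breaks (summary)

- Series shorter than one window, single-window SD, zero-variance response,
  rank-deficient designs, empty gene lists/backgrounds: errors with the
  offending quantity named.
- All-constant windows warn and yield zero maps; empty cluster tables and
  empty pSI candidate sets are valid results, not errors.
- All orderings that could tie (peak voxels, gene rankings, hub lists) have
  deterministic lexicographic tie-breaks, so identical inputs give identical
  outputs everywhere.
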