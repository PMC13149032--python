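# Methods

`mfispatial` re-implements, as a tested pipeline, the bespoke spatial and
statistical procedures used to analyse submicrometre spatial transcriptomics
of the human maternal–fetal interface (MFI): signed distances to anatomical
landmarks and niche composition, vessel-proximal EVT enrichment testing,
PDE3A×VIM endothelial state calling, a sparse-regression EVT invasiveness
score (iScore), local stromal-adjacency effects on invasiveness, and
toggle-switch classification of signed regulatory edges. Because the
primary data of this kind are controlled-access, the package ships a
synthetic tissue generator with planted ground truth; every estimator is
validated by recovering what was planted.

All coordinates are 0.5-µm pixels (1,000 px = 0.5 mm). All rank-sum tests
are two-sided Mann–Whitney tests (exact when both samples have ≤10 untied
values, tie-corrected normal approximation otherwise); multiple-testing
correction is Benjamini–Hochberg throughout.

## Geometry

**Signed distances.** The interface is a single-valued (x-monotone)
polyline with a declared maternal side; the unsigned distance is the exact
Euclidean minimum over segments (shapely), the sign comes from the
above/below test against the piecewise-linear interface height, with
endpoint fallback beyond the polyline's x-extent. Vessels are simple
polygons; the wall distance is signed + intraluminal / − extraluminal, and
nearest-vessel ties break to the lowest vessel id. Fetal-compartment cells
are flagged ineligible for vessel analyses. Distance bins are half-open
`[kW, (k+1)W)` with W = 100 px by default.

**Tile adjacency.** Cells are hashed to a square grid (default 50 px);
two cells are adjacent when their tiles are within Chebyshev distance
k = 5, giving a ~250–350 px (125–175 µm) reach — inside the usual 200-µm
paracrine range. Tile size is exposed because reasonable analyses may want
a tighter or looser neighbourhood.

**Depth matching.** Stratified sampling on 100-px depth bins draws, per
bin, `min(n_target, n_pool)` pool cells without replacement. When the pool
cannot cover a stratum, the matched *comparison* is restricted to the
common support: the target group is subsampled to the control set's exact
per-bin histogram, so the matched contrast compares identical depth
distributions by construction. The reported balance p-value is a rank-sum
test on the two matched depth vectors (expected non-significant).

## Vessel-proximal EVT enrichment

Per vessel, the observed statistic is EVT count in the outer wall annulus
(wall to w = 100 px) divided by the annulus area (outward polygon buffer
minus polygon). The null reference drops congruent annuli uniformly at
random into the maternal compartment (default 10 per vessel), rejecting
placements that leave the section, cross the interface, or intersect any
vessel lumen — lumen only, since the null regions must merely lack vessels.
Vessel and pooled null densities are compared by the two-sided rank-sum
test. Buffers use 64 quadrant segments, keeping annulus areas within
~10⁻⁴ of the analytic value for circular vessels. Calibration (rejection
rate at α = 0.05 within [0.02, 0.08] over 200 null sections) and power
(62 vessels at 3× planted annulus density, p < 0.01 in ≥95% of runs) are
exercised in the acceptance suite.

## Endothelial remodelling states

States are assigned by the quadrant rule on log1p-normalized PDE3A and VIM
(hi means value ≥ threshold): caEC (hi, hi) → R0 (PDE3A hi) → R1 (both
low) → R2 (VIM hi). Default thresholds are per-marker medians over the
section's endothelial cells; percentile or user-supplied thresholds are
available, and the method used is recorded. Marker separability uses the
rank-based (midrank-tie) AUROC over 10 bootstrap replicates. The spatial
validation computes per-state median |wall distance| with BH-corrected
pairwise rank-sum tests; on planted geometry the ordering is
caEC ≈ R0 < R1 < R2. Pseudotime reconstruction is not re-implemented: the
state order is taken as given and validated spatially.

## Composite DEG score and module scores

For groups a and b the composite score is

    S = log2((μ_a + 1)/(μ_b + 1)) × |Δpct|,

with means on library-size-normalized expression, and Δpct the difference
in percent expressing cells (percentage points). The |Δpct| weighting makes
S exactly antisymmetric under group swap — a raw signed product would be
symmetric and would rank strongly depleted genes alongside enriched ones.
Significance is a per-gene rank-sum test with BH correction. Marker
selection takes the top-n genes by S among FDR < 0.05, ties broken by
|log2FC| then gene id.

Module scores use expression-matched controls: genes are ranked by mean
expression into 25 equal-frequency bins and each signature gene draws up to
100 control genes from its own bin (never from the signature; capped with a
warning when a bin is small). Per cell, score = mean(signature) −
mean(pooled controls) on log1p-normalized values. Because controls share
the signature's expression stratum, library-size differences between cells
largely cancel in the subtraction. Score-distance association is Spearman's
ρ with its two-sided p.

## The iScore model

Vessel-associated EVTs (|wall distance| ≤ 200 px or an
endovascular/perivascular subtype label) are excluded; the rest are split
1:1 into train/test. Training cells are sorted by maternal depth |d_I|
(ties by cell id) and averaged in consecutive windows of k = 10 cells
(trailing remainder dropped); windows are the regression observations.
Features are standardized with training statistics only — held-out data can
never influence the fit, and the serialized model is byte-identical under
any perturbation of the test set. The model is an L1-penalized (LASSO)
regression of window depth on standardized window expression.

The penalty objective is `0.5·RSS + λ·‖β‖₁` (so on an orthonormal design
the solution is exact soft-thresholding of OLS, and λ = 0 reduces to OLS).
λ is chosen from a 30-point geometric grid (λ_max down to λ_max/100) by
5-fold cross-validated MSE with a *relative margin* rule: the largest λ
whose CV error is within 10% of the minimum. This deterministic parsimony
rule was preferred over both the CV minimum (which over-selects: dozens of
false positives against planted truth) and the classical 1-SE rule (whose
standard error, estimated from five fold errors, is unstable and
occasionally collapses to the dense CV-min solution); both alternatives
remain available (`selection="min" | "1se"`). The fitted intercept is
excluded from the score, being absorbed by per-section normalization.

Scoring: `iScore = Σ_g β_g (x_g − mean_g)/sd_g` over selected genes on
log1p-normalized single-cell expression, then normalized to mean 0 / sd 1
within each tissue section. Positive coefficients are pro-invasive,
negative anti-invasive. Validation is the Spearman correlation between
held-out single-cell iScores and observed depth. External matrices are
log1p-normalized and z-scored within the external dataset before applying
the trained coefficients; groups are compared by rank-sum test.

## Stromal adjacency contrasts

EVTs with ≥1 focal-subtype (DSC4) tile-neighbour form the focal group
(priority rule: a mixed neighbourhood counts as focal; an exclusive mode is
available); EVTs with only other-DSC neighbours form the second group;
EVTs with no DSC neighbour form the pool from which depth-matched controls
are drawn. Two rank-sum contrasts — focal vs other-adjacent, and
depth-matched focal vs matched controls — are BH-corrected as a two-test
family, with the depth-balance p reported alongside.

## GRN toggle classification

Signed TF→target edge lists (network inference itself is consumed as
input) are filtered at |coefficient| > 0.1 (strict), then classified by
(TF lineage, coefficient sign) into EVT/SCT × activation/repression.
Lineage TF sets come from composite-DEG tables (FDR < 0.01 and positive
score); TFs significant in both lineages are reported as the overlap and
their edges flagged shared. Target-gene contrasts compare per-gene mean
expression of each category's targets against the genome background
(genes expressed in ≥1% of the lineage's cells, targets excluded;
configurable), BH-corrected over the whole family. Shared-TF target
overlap is the Jaccard index of the two lineage-context target sets.

## The synthetic tissue generator

The generator is first-class, tested code; all generators are pure
functions of (config, seed) and byte-identical under seed reuse.

**Geometry.** A sinusoid-perturbed, x-monotone interface (amplitude 200 px,
period 2,000 px) splits a 6,000×6,000-px section into fetal villi (VCT,
SCT, uniform) and maternal decidua. Vessels are circles (radius 150 px,
256-gon, ≥300 px from the interface and borders, non-overlapping). EVT
placement density decays exponentially with depth *above the local
interface height* (scale 1,000 px; exact polyline-distance decay on a flat
interface) and is multiplied by 3 inside the 100-px perivascular zone.
Endothelial cells sit on vessel walls at state-dependent outward offsets
(caEC/R0 ≈ 5 px, R1 ≈ 30 px, R2 ≈ 120 px, with jitter). Annotated DSCs are
deliberately sparse (150 cells: mapped subtype-confident cells, not the
full stromal mass) so that EVTs outside any DSC neighbourhood exist —
otherwise no depth-matched control pool is definable at the 5-tile reach;
DSC4 cells cluster in superficial patches near the interface, mirroring
their localization at anchoring-villus termini. Immune cells are uniform
fillers.

**Expression.** Counts are negative binomial with gene-level log-means:
a N(−0.5, 1) generic baseline, 10 mitochondrial genes, and 150
high-expression housekeeping genes (log-mean 2.2) that give module scoring
a depth-independent control stratum at the planted programs' expression
level. Planted programs:

* *Invasion program* — 40 genes whose EVT log-mean changes linearly with
  depth (|slope| ~ U(0.5, 0.9) per 1,000 px, random sign). Anti-invasive
  (negative-slope) genes start high at the interface inside EVTs
  (baseline + |s|·2.5), so their decline is measurable across the full
  depth range rather than bottoming out; outside EVTs they sit at the
  plain baseline. Program genes are transcriptionally bursty (their own
  NB dispersion θ = 0.5 versus 5 elsewhere). Both choices matter for
  recoverability: with low-noise, floor-clipped features the 40
  depth-driven genes are nearly collinear at the window level and an L1
  selector keeps only a few representatives — a property of the l1
  penalty, not of the data processing.
* *Endothelial mimicry* — 100 genes (log-mean 2.2, +1.5 in endothelium)
  elevated in EVTs near vessel walls with a plateau–exponential profile:
  full amplitude 0.8 within 100 px of the wall, decaying with a 200-px
  length beyond. The high baseline is required for a log-mean shift to
  survive the log1p transform of counts.
* *Endothelial states* — per-state PDE3A/VIM log-means (hi = 2.5,
  low = 0.0) on the planted caEC/R0/R1/R2 labels.
* *DSC4 suppression* — EVTs within 250 px of a DSC4 cell have their
  invasion program shifted *down the program axis*: depth-increasing genes
  by δ, depth-decreasing genes by −δ. (A uniform shift of all program
  genes would largely cancel in any signed invasiveness readout.) The
  default δ = −0.3 models a modest everyday effect; detection experiments
  plant δ = −1 explicitly.

**GRN.** `generate_grn` emits signed TF→target edges in four categories
(EVT/SCT × activation/repression) with the category mix defaulting to the
observed composition of the trophoblast toggle network, coefficient
magnitudes bounded away from the 0.1 filter threshold on both sides, and a
configurable below-threshold fraction for filter testing.

**What the generator does not emulate.** Segmentation error, doublets and
ambient RNA, batch and chemistry effects, spatial autocorrelation of
expression beyond the planted programs, realistic cell-type marker
hierarchies, irregular vessel shapes, and tissue folds/tears. Passing
tests therefore demonstrate that the estimators recover the targeted
effects under clean geometry and NB noise — not robustness to the full
messiness of real sections.

## Problem sizes and reproducibility

Acceptance-level experiments run at the package's default study
conditions: 3,000 genes with 40 planted invasion genes, 4,000 EVTs per
section, 10-cell windows with 5-fold CV (iScore); 62 vessels with 10 null
draws each (enrichment power) and 200 smaller null sections (calibration);
800 endothelial cells across 4 states; 100-signature exchangeability nulls;
100 depth-confound null simulations for the adjacency contrast. All
randomness flows from explicit integer seeds; `scripts/acceptance.py`
derives every sub-seed from its `--seed` argument.

## Known limitations

* The interface must be single-valued in x; convoluted or multi-valued
  boundaries would need a different sign convention.
* LASSO gene selection on strongly collinear programs under-selects by
  design; sensitivity claims hold at the generator's noise level.
* The composite DEG score saturates for genes expressed in ~100% of both
  groups (|Δpct| → 0); such genes rank low regardless of fold change.
* Exact rank-sum enumeration is used only for small untied samples; with
  ties the tie-corrected normal approximation is applied at any n.
* Null-annulus sampling can overlap perivascular zones of *other* vessels
  (only lumens are excluded), slightly biasing the null upward — i.e. the
  enrichment test is conservative.
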