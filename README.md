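# mfispatial

Spatial and statistical analysis of the human maternal–fetal interface
(MFI) — the tissue where fetal extravillous trophoblasts (EVTs) invade the
maternal decidua and remodel uterine spiral arteries. The package
implements, as an importable library, the analysis chain used on
submicrometre spatial transcriptomics of basal-plate sections:

* **Geometry** — signed distances of every cell to the interface polyline
  (+ maternal / − fetal) and to the nearest vessel wall (+ intraluminal /
  − extraluminal), distance-binned cell-type composition, grid-tile
  adjacency, and depth matching.
* **Vessel enrichment** — EVT density in vessel-wall annuli versus
  randomized congruent decidual regions (two-sided Wilcoxon rank-sum).
* **Endothelial states** — caEC → R0 → R1 → R2 remodelling states from
  PDE3A × VIM quadrants, bootstrap AUROC separability, and spatial
  validation of the state ordering by wall distance.
* **Signatures** — composite differential-expression score
  S = log2FC × |Δpct|, marker selection, and bin-controlled module scores
  (e.g. the endothelium-like score of vessel-adjacent EVTs).
* **iScore** — a sparse-regression invasiveness score: depth-sorted
  10-cell pseudobulk windows, leakage-safe standardization, L1-penalized
  (LASSO) regression of decidual depth on expression, per-section
  normalized single-cell scores, held-out Spearman validation, and
  external-dataset benchmarking.
* **Neighbour effects** — iScores of EVTs adjacent to a decidual stromal
  subtype (DSC4) versus other-adjacent and depth-matched non-adjacent
  controls.
* **GRN toggle** — classification of signed TF→target edges into
  EVT/SCT × activation/repression, target-expression contrasts against
  genome background, and Jaccard overlap of shared-TF target sets.

Because the motivating data are controlled-access, the package includes a
first-class **synthetic tissue generator** (`mfispatial.synthetic`) that
plants every effect above with known ground truth — depth-decaying EVT
placement, perivascular enrichment, endothelial state geometry and
markers, a depth-linear invasion program, endothelial mimicry near vessel
walls, local DSC4 suppression, and four-category regulatory edge lists —
so the whole pipeline is testable end-to-end.

## The model at the core

For EVTs away from vessels, cells are sorted by decidual depth |d_I| and
averaged in windows of k = 10 cells; the iScore model is the LASSO

    min_β  ½ Σ_w (d_w − β₀ − z_wᵀβ)²  +  λ‖β‖₁

over standardized window expression z, with λ chosen by 5-fold
cross-validation (largest λ within 10% of the minimal CV error). A single
cell's invasiveness is iScore = Σ_g β_g (x_g − mean_g)/sd_g, normalized to
mean 0 / sd 1 within each section; β_g > 0 marks pro-invasive genes,
β_g < 0 anti-invasive ones.

## Worked example

```python
from mfispatial import pipelines

rec = pipelines.iscore_recovery(seed=0)
print(f"selected genes: {rec.n_selected}")
print(f"sensitivity vs the 40 planted invasion genes: {rec.sensitivity:.2f}")
print(f"false selections: {rec.false_selections}")
print(f"held-out Spearman rho(iScore, depth) = {rec.heldout_rho:.2f} (n = {rec.n_test})")
```

prints, on the default synthetic section (4,000 EVTs, 3,000 genes, 40
planted invasion genes):

```
selected genes: 44
sensitivity vs the 40 planted invasion genes: 0.88
false selections: 9
held-out Spearman rho(iScore, depth) = 0.79 (n = 1785)
```

i.e. the cross-validated model recovers 35 of the 40 planted
invasion-program genes with 9 spurious picks, and its single-cell scores
track true invasion depth on held-out cells with ρ ≈ 0.8. The
`examples/` directory has one narrative script per capability
(simulation + QC, composition profiles, vessel enrichment, endothelial
states, pseudovascularization scoring, the iScore, DSC4 adjacency, and GRN
toggle classification); each prints the numbers it computes and what they
mean.

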