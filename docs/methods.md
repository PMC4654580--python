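# Methods

This note documents the models, parameter choices and known limitations
of the package, in the order data flows through the pipeline.

## Stain model and unmixing

Brightfield transmission is modeled by Beer–Lambert: per-channel optical
density `OD = −log10((I + 1)/255)` with a one-intensity-unit guard so
saturated pixels stay finite; negative OD (pixels brighter than the
white point) is clipped to zero. A pixel's OD vector is a non-negative
combination of unit stain OD vectors. We use the Ruifrok–Johnston H-DAB
calibration (hematoxylin (0.650, 0.704, 0.286), DAB (0.269, 0.568,
0.778), both normalized), completed to an invertible basis by their
cross product. Unmixing is a 3×3 linear solve with negative
concentrations clipped to zero. The synthetic renderer uses the *same*
forward matrix, so round-trip recovery tests exercise the inversion
against a matched generative model; on real slides the vectors are
configurable per batch.

## Nucleus detection and positivity

The commercial software used in the original analysis is closed source;
its "IHC threshold" scale is undocumented. This package defines it as
**mean DAB optical density per nucleus** (a 0–~2 scale) and keeps the
published numeric defaults: 0.3 for CD3 and CD20, 0.5 for CD138, κ and
λ, and 0.4 for the pixelwise marker-area threshold. This preserves the
original parameterization while giving it a reproducible physical
meaning.

Detection pipeline (all parameters overridable):

* combined nuclear signal = hematoxylin + DAB concentration, so strongly
  DAB-masked nuclei are not lost;
* Gaussian smoothing, σ = 1 µm;
* Otsu threshold computed within the ROI only (a flat ROI returns "no
  nuclei" rather than thresholding noise);
* distance-transform watershed with seed separation 2.5 µm to split
  touching nuclei;
* area filter 10–200 µm²; only nuclei whose centroid lies inside the ROI
  are kept. All detected nuclei passing the filter are counted — no
  shape-based mononuclear filter is applied, since the original method's
  behavior on that point is unspecified.

Densities use two distinct first-class masks: the submucosal ROI (lamina
propria plus muscularis propria when present) for cell densities, and
the whole-specimen mask for the epithelium/specimen area ratio. Areas
are `pixel_count × mpp²/10⁶` mm²; the default calibration is 0.46 µm/px,
a typical 20× whole-slide scan (the original scan resolution is not
stated).

## Rule layer

* Lymphoplasmacytic density = CD3 + CD20 + CD138 densities.
* Plasma cell ratio = 100·CD138/total; undefined (NaN, flagged) when the
  total is zero — never silently 0.
* Inflammation: inflamed iff density ≥ 200 cells/mm². The boundary is
  taken inclusive (the source analysis wrote both ">200" and "<200"; a
  single documented convention is required and no printed specimen sits
  on the boundary).
* Light-chain restriction: κ:λ ratio strictly outside [0.7, 5.5] *and*
  total light-chain density strictly > 50 cells/mm². The floor is
  interpreted as κ+λ (the union reading of "light-chain-positive
  cells"); with λ = 0 the ratio is +∞ (restricted if the floor is met),
  with both chains 0 the ratio is undefined and the biopsy is polytypic.
  Calls are scale-free in the ratio: joint rescaling of (κ, λ) that keeps
  the floor satisfied never flips a call.
* Case aggregation ignores not-evaluable biopsies rather than discarding
  the case: positive if ≥1 evaluable biopsy restricted, negative if ≥1
  evaluable and none restricted, not-evaluable only when every biopsy
  is. This matches the published per-case grid, where a case with one
  unevaluable biopsy is still counted through the other.

## Statistics

* **Fisher's exact test** (2×2): two-sided by the point-probability
  method — the sum of hypergeometric probabilities ≤ that of the
  observed table. Probability comparisons are done on exact integer
  weights `C(r1,a)·C(r2,c1−a)`, so ties at the observed probability are
  decided exactly, not by floating-point luck.
* **χ² test for trend** (2×K, K ≥ 3): Cochran–Armitage with equally
  spaced scores, the finite-population (hypergeometric, N−1) variance,
  no continuity correction, referred to χ²(1). The standardized
  statistic is invariant under affine rescaling of the scores. The
  asymptotic p approximates the *mid-p* tail of the exact conditional
  permutation distribution; at small N the discrete atom at the observed
  statistic (easily 0.01–0.06) bounds the achievable agreement with any
  permutation estimate, so oracle validation is done in the asymptotic
  regime (large null-drawn tables), plus an exact-enumeration spot check
  on a small table.
* **Mann–Whitney**: exact tie-aware enumeration over all group
  assignments when both groups have ≤ 8 observations, with the two-sided
  p defined as twice the smaller inclusive tail, capped at 1 (the null
  distribution of U is symmetric, ties included); otherwise the
  tie-corrected normal approximation without continuity correction.
* **Spearman**: tie-averaged ranks with the t-approximation on n−2 df
  (delegated to scipy).
* Group-comparison dispatch is heuristic — binary variables to Fisher,
  ordered ≥3-level variables to trend, continuous to Mann–Whitney —
  because the original report does not state which test produced each
  printed value. Two printed p-values in the eye-graded histology table
  are inconsistent with their own printed counts under any standard
  test; the consistency test therefore asserts numeric agreement for
  non-significant rows and direction-level agreement for significant
  ones.
* Percentages are printed to one decimal, rounding half up.

## Synthetic data

**Slides.** Tissue is a filled ellipse (≈66% of the frame); an optional
epithelium band occupies a target fraction of the tissue area (used for
cytokeratin-style slides). Cells are disks (default radius 7 px) placed
uniformly at random in the submucosa by rejection sampling with a
minimum center distance of 1.5 radii (overlap depth ≤ half a radius);
an infeasible request raises an error reporting the achievable maximum.
All nuclei receive hematoxylin OD 0.6 over a 0.08 tissue counterstain;
positive cells receive DAB OD 0.8 and negatives 0.05 — well separated
relative to the 0.3–0.5 thresholds, which is what the ≥99% positivity
agreement figure demonstrates (it is a statement about the scoring rule,
not about ambiguous real-world staining). Ground truth (centers,
classes, masks, exact planted density) is exact by construction; a
single seed makes renders bit-identical.

**Cohorts.** Groups follow the published design: NHIC and non-IC
cystitis cases contribute one biopsy, HIC cases a background (BG) and a
Hunner-lesion (HL) biopsy — 27 HIC + 39 NHIC gives the published 93 IC
specimens from 66 patients. Per-marker densities are log-normal per
group. Since the original per-specimen values are unpublished (figures
only), the parameters are calibrated to the published binned cross-tab:
NHIC medians (42, 16, 8) cells/mm² for (CD3, CD20, CD138) with
sdlog 0.85 put ~93% of NHIC specimens below 200 cells/mm²; HIC medians
(220, 100, 80) (BG) and (240, 110, 90) (HL) with sdlog 1.45 reproduce
the ~7% / 53% / 40% split across the <200, 200–1000 and >1000 bins. A
plasma-ratio shift (+0.10 of the CD138 share, holding CD3+CD20 fixed)
reproduces the higher plasma cell ratio of HIC. Light chains are
log-normal with a 2:1 κ:λ baseline and sdlog 0.3, keeping the unskewed
false-flag rate ~1%. Each HIC case carries a clone with probability 0.3;
the clone multiplies one chain by 20 in one biopsy (occasionally both,
reflecting that clonal expansion is usually focal). Biopsies are flagged
not-evaluable for ISH with probability 0.15 (≈ the published 46/54
evaluable fraction). Epithelium ratios are scaled-beta on [0, 25]% per
group; the epithelial-loss fraction used for eye-style grading is
derived against a 20% fully-epithelialized reference. Eye-style grades
map density through boundaries (250, 1100) cells/mm² — chosen so grade 0
falls mostly below 200 and grade 2 mostly above 1000, as in the
published cross-tab — and epithelial loss through the thirds rule with
exact thirds assigned to the higher grade ("a third to two-thirds lost"
reads inclusive on the low end).

What the generator does **not** emulate: nuclear morphology beyond
disks, stromal texture, fibrosis/edema, mast cells, staining gradients,
scanner noise, or correlated marker densities within a specimen beyond
the plasma-ratio shift. Passing recovery tests therefore demonstrates
correctness of the measurement chain under the stated forward model, not
performance on real histology.

## Problem sizes and numerical choices

Validation uses 768×768 px slides at 0.92 µm/px (~0.33 mm² of tissue),
20 seeds per condition, planted densities 50–1000 cells/mm² — a regime
where rendering plus quantification runs in under half a second per
slide while cell counts per slide (17–330) keep relative counting error
meaningful. Clone-detection operating characteristics use 1000 simulated
biopsies. The Fisher oracle sweep enumerates all 2×2 tables with N ≤ 40
exactly. Degenerate inputs are errors, not silent zeros: empty ROI,
zero-area specimen mask, empty samples, constant input to Spearman, and
invalid configurations (e.g. ratio_low ≥ ratio_high) are all rejected
with descriptive exceptions before any stage runs.

## Known limitations

* The IHC-threshold scale is this package's reconstruction; absolute
  densities from the original commercial tool are not expected to be
  numerically identical on real slides, though the rule layer is
  threshold-parameterized and the published defaults are preserved.
* No pyramidal whole-slide format support; images must fit in memory.
* Which statistical test produced each published group-comparison
  p-value is unknown; the dispatch heuristic reproduces most printed
  values to ~4 decimals but two printed values appear to be typographic
  errors (see the statistics section).
* Figure-only distributions from the original cohort are emulated, not
  reproduced; fixture-based reproduction covers the printed count grids
  and summary fractions only.
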