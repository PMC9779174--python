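# Methods

## Problem and model

Desert grassland monitoring from consumer RGB cameras rests on a chain of
approximations: a visible-band vegetation index projects each pixel's
colour to a scalar; a global threshold splits the scalar field into
vegetation and non-vegetation; the vegetation pixel fraction (FVC, in
percent) keys a five-grade desertification scheme; and the quality of the
whole chain is judged against a supervised per-pixel classification that
uses the full 3-D colour information. This package implements every link
of that chain and the statistics used to compare the 19 indices per grade.

### Vegetation indices

Indices operate in one of two input spaces. *Chromatic* formulas use
brightness-normalised coordinates r = R/(R+G+B) etc., which removes global
illumination scaling; *raw* ratio formulas (GLI, NGBDI, NGRDI, MGRVI,
RGBVI, EGRBDI, DEVI) are themselves scale-free ratios of digital numbers.
All 18 ratio-form indices are invariant under global intensity scaling;
this is asserted by tests. Degenerate pixels are mapped to neutral values
(black pixel → chromatic (1/3, 1/3, 1/3); any ratio with zero denominator
→ 0; VEG → 0 where r or b is 0) so index maps are always finite.

Three published formulas needed interpretation, resolved as follows:

* **CIVE** uses the green coefficient 0.881 as published in the source
  table (the value in wider circulation is 0.811); it is a named constant
  and can be overridden per call or through `RunConfig.cive_green`.
* **V-MSAVI** is implemented in the canonical MSAVI template on chromatic
  coordinates, (2g + 1 − √((2g+1)² − 8(2g − r − b)))/2, with the radicand
  clamped at 0 (the printed expression is not a well-formed equation).
* **DEVI** is read literally as (G + R + B)/(3G), 0 where G = 0, and **g**
  as the green chromatic coordinate.

### Otsu segmentation and polarity

The threshold maximizes σ_B²(t) = ω₀(t)ω₁(t)(μ₀(t) − μ₁(t))² over a
histogram of `n_bins = 256` equal bins spanning [min, max] of the index
map (configurable; 256 matches the 8-bit heritage of the imagery).
Candidate thresholds are interior bin edges; ties break toward the
smallest threshold for determinism. A constant map is rejected as
degenerate. Tests verify the maximizer against an exhaustive search over
all midpoints of adjacent distinct values: the comparison is on the
achieved between-class variance, because any cut inside the same empty
histogram valley induces the same partition.

Some indices are vegetation-high (ExG), others vegetation-low (ExR, RGRI,
CIVE, GBRI, ExB), so the vegetation side of the threshold is resolved per
image: the class with the higher mean green chromatic coordinate is
vegetation (tie → above-threshold class; per-index manual override
available). This makes segmentation invariant to negating an index map.

### Grading

The five published FVC bands are integer-valued ("5–20%", "21–50%", …) and
leave real-valued gaps; grading uses the half-open partition
[0,5), [5,21), [21,51), [51,71), [71,100] so every FVC receives exactly
one grade. This reproduces all 30 published survey rows
(`desertfvc.datasets`).

### Reference classifier

A per-scene RBF-kernel SVM on per-pixel raw (R, G, B) features, trained on
60+60 single-class ROIs, with test (15+15) and validation (80+80) ROI
roles disjoint from training. Features are scaled to [0, 1] before the
kernel, where the configured width γ = 0.333 (= 1/n_features, the common
default) describes a sensible kernel; on raw 0–255 digital numbers the
same γ would collapse the kernel to near-nearest-neighbour behaviour.
"Probability threshold 0" is read as *no rejection class*: every pixel
gets the argmax label. Training pixels are capped at 10 000 per class by
seeded subsampling; optional chromatic features can be appended via
config. The regularisation constant stays at the library default (C = 1).

### Accuracy metrics

OA and kappa are computed over validation-ROI pixels only (vegetation =
positive). Kappa uses the general r×r form, which tests confirm equals
the binary computation on 2×2 counts. RE = (V_SUP − V_VI)/V_SUP is stored
signed together with |RE|; grade-level aggregation and ANOVA use |RE|,
since signed averaging lets over- and under-estimates cancel, contradicting
the "smaller is more accurate" reading. OA is stored as a fraction and
reported in percent.

### Grade-wise ANOVA and Duncan letters

Per grade and metric the 19 indices × 6 images form a balanced one-way
layout (df 18/95/113). The ANOVA is the textbook sum-of-squares
decomposition with p from the F distribution. MS_within = 0 with zero
between-group spread reports F = 0 (p = 1); with non-zero spread F is
undefined and reported as NaN with a diagnostic.

Duncan's multiple range test compares sorted means over spans p = 2..k
with critical range R_p = q*(p, df_within)·√(MS_within/n), where q* is the
studentized-range quantile at the protection level 1 − (1−α)^(p−1)
(α = 0.05), computed from `scipy.stats.studentized_range` rather than
interpolated from historical tables. Letters come from the standard
step-down underlining algorithm: spans are examined widest first, a span
whose extreme difference falls below R_p is declared homogeneous together
with everything inside it, and maximal homogeneous intervals receive
letters in order of descending mean (ties broken by input order).
Unbalanced groups are rejected — the design is balanced. p-values are
reported to 3 decimals in the CSV output, "0.000" meaning < 0.0005.

## Synthetic scenes

No imagery is distributed with the package; a seeded generator provides
scenes whose *statistical* structure matches what the pipeline assumes:

* **Geometry.** Vegetation is a union of random rotated ellipses (radii
  6–24 px) laid down until the truth-mask FVC reaches the target; a patch
  that would overshoot the tolerance band (default ±2 FVC points) is
  shrunk. Targets above 50% generate the soil complement instead, so the
  achieved FVC always lands at or slightly above the target — symmetric
  behaviour on both sides of a grade boundary. Scenes are regenerated with
  a derived sub-seed in the rare case the achieved FVC crosses a grade
  edge. Default size 512×512 (real UAV frames are far larger; this keeps a
  30-scene study around a minute of CPU).
* **Colour.** Vegetation N((70, 120, 55), 4²I) over soil
  N((160, 140, 105), 4²I), plus additive sensor noise (sd 2). The sd
  models within-material chromatic spread — real grassland materials are
  chromatically consistent, their large intensity variation being mostly
  spatially structured brightness — and is set so that every endorsed
  index keeps a valley-winning Otsu margin at the severe grade's extreme
  (≈2%) class imbalance, the regime in which these indices demonstrably
  work on real surveys. The `spectral_overlap` knob interpolates the
  vegetation palette toward soil and is the designated difficulty control.
* **Confuser material.** 6% of each class is mild texture (pull 0.15–0.4
  toward a confuser colour, staying on its own side of index thresholds).
  Independently, per scene a seeded fraction up to 1.2% of the vegetation
  is rendered fully dry (brown-yellow (115, 100, 65)), and green-yellow
  litter with pixel count up to 1.2% of the *vegetation area* is scattered
  over the soil (litter mass scales with cover). Both confusers stay
  closer to their own class in 3-D RGB — the SVM reference classifies them
  correctly — but sit on the wrong side of typical index thresholds in
  green chromaticity. The two independent draws give every index a signed,
  cover-independent FVC error bounded at roughly ±1.2%, so relative errors
  straddle zero at every grade, as a roughly unbiased pipeline should.
  The litter colour is defined relative to the effective palettes (62% of
  the way to vegetation plus a bright-yellow off-axis offset) so it remains
  soil-like in 3-D at every overlap.
* **Panel.** The default study panel holds 6 scenes per grade with target
  FVCs at fixed per-grade base values plus small seeded jitter, spread the
  way a real survey's images spread through each band — in particular a
  single non-desertification scene above 90% cover. The
  non-desertification grade uses spectral overlap 0.45 (vs 0.15
  elsewhere): dense cover is where vegetation and soil colours intermix,
  and where the index pipeline visibly breaks down (the ~96%-cover scene
  is misgraded by design at most seeds, and grade-wise ANOVA turns
  non-significant there, while remaining significant at severe–slight).
* **ROIs.** Training/test/validation ROIs are non-overlapping axis-aligned
  squares sampled from pure-class regions of the truth mask; validation
  ROIs total 12% ± 1% of the image, split between classes in proportion to
  class prevalence (scarce classes get proportionally small reference
  regions, as a human analyst would draw them). Placement uses integral-
  image purity checks with automatic size shrinkage in scarce classes.

What passing tests on these scenes does **not** show: robustness to
spatially structured texture, cast shadows with geometry, mixed pixels at
real patch boundaries, illumination gradients, or any radiometric effects
— the generator draws pixels independently given the material layout. The
shadow knob (`shadow_fraction`, default 0) only darkens random vegetation
pixels. Results on real imagery will be worse than on these scenes;
the package validates the *arithmetic and statistics* of the pipeline,
and the generator's difficulty knobs probe failure modes qualitatively.

## Numerical and design choices

* All index arithmetic in float64 (squared-channel indices overflow 8-bit
  integers).
* Otsu bins 256; tie-break toward the smallest threshold; the bin-centre
  approximation satisfies total = within + between variance to 1e-6.
* Per-scene failure isolation: a degenerate Otsu input (constant index
  map) aborts the run by default; with `skip_degenerate` the cell is
  recorded missing and the ANOVA then refuses the unbalanced grade.
* All randomness flows from one root seed through
  `numpy.random.SeedSequence.spawn`, split per scene and stage; every
  operation is a pure function of (spec, seed), and reruns are
  bit-identical.
* Pixel conventions: 0-based row-major indices, origin top-left,
  half-open intervals.
* Masks are written as 0/255 PNG; ROIs round-trip through labelled-mask
  PNGs or a polygon text file (rectangles rasterised inclusively).

## Known limitations

* The Otsu step inherits the method's class-imbalance bias: below ~2%
  or above ~98% true cover, or under heavy spectral overlap, the
  maximizer can split the dominant mode instead of the class valley and
  the FVC estimate collapses (this is the mechanism behind the
  non-desertification failure, and it is genuine, not an artefact).
* Duncan letters depend on the studentized-range quantile; for very large
  k and small df the scipy quantile solver dominates runtime.
* The SVM reference is only as good as the ROI labels; with the synthetic
  truth masks it is near-perfect, which real hand-drawn ROIs are not.
* NIR-based indices (NDVI, SAVI, …), radiometric calibration, mosaicking,
  texture and learned classifiers are out of scope.
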