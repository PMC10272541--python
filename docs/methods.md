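# Methods

## Spatial conventions

All modules share one pixel grid: origin top-left, `(row, col)` indexing,
boolean masks with `True` = foreground.  The default pixel pitch is
200/512 = 0.390625 µm (a 20× tile of 200×200 µm² at 512×512 px); every
physical quantity is derived from pixel counts via this pitch, so the same
pixel content at a doubled pitch reports doubled lengths and widths.
Region annotation is a label image (0 background, 1 central vein, 2 portal
tract, 3 perisinusoidal); the three regions partition the tissue mask.
When no annotation is supplied, tissue is estimated from TPEF (pixels
above 5% of the 99th-percentile intensity, holes filled, components
< 1000 µm² dropped) and the whole tissue is treated as perisinusoidal —
parameters suffixed `PS` then simply cover the tissue.

## Steatosis

**Dark threshold.**  Vacuole candidates are the dark connected components
of TPEF inside tissue.  The threshold is Otsu's between-class-variance
maximizer on the tissue-restricted histogram (lower class = dark), guarded
by a bimodality test: the split is accepted only if the class means differ
by ≥ 33% of the upper mean *and* by ≥ 6 pooled within-class standard
deviations.  The second criterion matters because an Otsu split of a
unimodal Gaussian separates its halves by only ≈ 2.7 such deviations, so
without it a noise-only image would "segment" a large fraction of pure
noise.  When the guard rejects the split, a fixed fallback of
0.35 × median(tissue) is used, which finds nothing in a vacuole-free
image.  The identical guard protects collagen segmentation in SHG, where
stage-0 images can be essentially signal-free; there the degenerate case
returns an empty mask with a warning instead of an error.

**Hole filling.**  Only enclosed bright pockets smaller than 0.8 µm² are
filled.  A blanket fill would merge tightly packed vacuoles through the
bright interstitial pockets between them, destroying per-object detection
in severe steatosis.

**Classification.**  Each candidate (area ≥ 3 µm², shape features from
`skimage.regionprops`, circularity 4πA/P² with the Crofton perimeter,
clipped to 1.05 for rasterization) is labeled by a binary decision tree.
The default tree rejects circularity < 0.4 or solidity < 0.7 (cracks,
sinusoids), rejects equivalent diameter < 2 µm, and cuts macro from micro
at 10 µm.  All cuts are config-exposed, and a trained tree in the same
nested-dict form can be loaded to replace the default; a
collagen-density-near-the-boundary feature is computed when a collagen
mask is supplied, for use by such trees.  Candidates overlapping vessel
lumens are rejected outright (dark holes, but not fat); border-touching
candidates are excluded from all area parameters.  `%Area` counts vacuole
pixels only (not the dilated steatosis region); `%MacroArea + %MicroArea =
%Area` holds exactly because the class masks partition the counted pixels.
The steatosis *region* is the vacuole mask dilated by a disk of physical
radius (default 10 µm ≈ one hepatocyte radius), implemented as a Euclidean
distance-transform threshold, which is exact for non-integer radii.

## Fibrosis

Collagen segmentation removes components < 2 µm² after thresholding.  The
resulting area percentage of tissue **is** the CPA analog — computed from
SHG, not from a Sirius-red stain.  Strings are 8-connected components;
morphology comes from a medial-axis skeleton: length is the sum of step
lengths (1 px or √2 px) over adjacent skeleton-pixel pairs, skipping a
diagonal step when the two pixels share an orthogonal skeleton neighbour
(otherwise every corner would be counted 1 + √2 instead of 2).  This
estimator is accurate to ≈ 2% on drawn stencils.  Mean width is component
area / skeleton length; branch points are skeleton pixels with ≥ 3
skeleton neighbours; region is the majority vote of component pixels.

The qualitative string attributes are explicit thresholded predicates
(exact numeric definitions for them are not published; these defaults are
documented stand-ins whose ordinal behaviour is what the downstream
analysis uses): *long* ⇔ length ≥ 40 µm, *thin* ⇔ mean width ≤ 1.5 µm,
*aggregated* ⇔ ≥ 2 other string centroids within 20 µm, *distributed* ⇔
not aggregated.  All four thresholds are config keys.

## Co-localization

The neighbourhood of a steatosis class is its vacuole mask dilated by the
co-localization distance (default 10 µm, unpublished in the original
description, config-exposed) intersected with the perisinusoidal region.
Area fractions use pixel-level intersection (measure semantics); count
parameters use whole-string attribution — a string counts when ≥ 50% of
its pixels fall inside the neighbourhood (object semantics).  A `clip`
attribution mode (any overlap counts) is also implemented.  String flags
are *not* recomputed on the restricted subset; this guarantees the subset
dominance property (every co-localized count ≤ its unrestricted
counterpart), which recomputation could violate through the
aggregated/distributed complementarity.

## Indices

Features are ranked per cohort by |Spearman R| against the ordinal score
(ties broken alphabetically, constant columns forced last with R = 0).
Shared features are the intersection of every cohort's top-k (default
k = 10, escalated by 5 until non-empty); with a single cohort the top-k is
used directly.  The index is ordinary least squares of the score on
z-scored features — "linear model" is interpreted as OLS on the ordinal
score because evaluation uses only rank statistics (Spearman, AUC), for
which any monotone scale is equivalent.  Constant and duplicated columns
are pruned before fitting, the feature count is capped at n−2 to keep the
fit overdetermined, and a rank-deficient design raises an error naming the
collinear columns.  Indices can be fitted pooled or per cohort; pooled is
the default.

## Evaluation

Spearman uses midranks with the t-approximation for p (the exact
permutation p is not implemented); constant inputs are an error.  AUC is
the Mann–Whitney statistic U/(n₀n₁) with ties counted ½, identical to the
trapezoidal area under the empirical ROC; a dichotomy with an empty side
yields NA rather than an exception, matching report tables for cohorts
that never reach (or never avoid) a given stage.  AUCs are reported
unflipped — orienting the index is the model's job — and p-values carry no
multiple-testing correction.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not photorealistic histology.

*Intensity model* — tissue TPEF ~ N(160, σ), vacuole interiors and vessel
lumens ~ N(20, σ), SHG background ~ N(8, σ), string amplitude 180 with a
Gaussian blur of 0.6 px for anti-aliasing; σ = `noise_sd` (default 8,
range chosen so that Otsu separation is easy at σ = 0 and realistic at the
default).  All randomness flows through one `numpy` generator seeded from
the spec, so identical spec + seed gives bit-identical images.

*Vacuoles* — ellipses with axis ratio in [0.8, 1], equivalent diameter
sampled uniformly from the class range (macro 12–40 µm, micro 2–8 µm; both
deliberately clear of the 10 µm classification boundary).  Placement is a
greedy best-fit packer: diameters are pre-sampled to meet each class's
area budget (the last draw clamped to the remaining budget), sorted
descending, and placed at a random pixel whose free-space clearance just
fits; when no gap-respecting spot exists the packer allows touching and
finally bounded overlap (≤ 10% of the smaller area), which is what makes
grade-3 targets of 70% reachable.  Overlap pixels stay with their first
owner, so per-class pixel counts are exact and macro + micro = total area
holds identically.  A target is declared infeasible (error reporting the
achieved area) only when the shortfall exceeds what whole-object
quantization explains — on small canvases a class budget can be smaller
than half of one minimum-size vacuole, and the sample is then legitimately
short.

*Collagen* — per-stage presets place three string populations: isolated
long strings (50–90 µm, kept ≥ 45 µm from every other centroid so they
stay "distributed"), aggregated clusters of 3–6 members, and short
background strings (vessel-rim only at stage 0).  Counts
(0/2/4/7/10 long, 0/1/2/4/6 clusters, 4/8/12/16/20 short for stages 0–4),
mean lengths and mean widths are all non-decreasing in stage; stage 4 adds
two bridging strings oriented between the vessel centers.  The numeric
preset values are design choices — no quantitative stage-wise collagen
morphology is published — fixed once to make the four shared parameters
monotone with comfortable margins.  Uncoupled clusters are parallel
bundles (6.5 µm spacing, septa-like); coupled clusters wrap tangentially
around a chosen macro vacuole on three radial tiers, with a radial
correction against the true distance map so every member centroid stays
within the co-localization distance of the elliptical boundary.  Strings
other than cluster members carve a 21 µm spacing disk around themselves,
so they are distributed by construction; satisfying the coupling band
outranks the spacing carve when the two conflict, which makes the
coupling = 1 / coupling = 0 guarantees exact in uncrowded samples.

*What it does not emulate* — real tissue texture, inflammation foci,
ballooning, vessel-tree topology, partial-volume and depth effects,
imaging vignetting, or pathologist disagreement.  Passing tests therefore
demonstrate that the measurement chain recovers known structure under the
stated intensity model; they do not certify performance on real slides.

## Problem sizes and numerics

Unit tests run on 192–256 px canvases; end-to-end checks use the native
512 px tile (one sample per grade for steatosis recovery; stages 0–4 × 5
samples for fibrosis recovery), 384 px tiles for the coupling contrast
(n = 5 per arm), and one hundred 192 px samples for the subset-dominance
sweep — sizes chosen to exercise every code path at full fidelity while
keeping a complete run within a few minutes on one CPU.  Ties in the Otsu
maximizer break toward the smallest threshold; foreground is strictly
greater than the threshold.  CSV round-trips use 12 significant digits.
The pipeline's only random stage is generation; a single run seed is
expanded to per-sample seeds by fixed offsets, making `params.csv` and
`report.csv` byte-reproducible.

## Known limitations

* The macro/micro decision tree is a transparent stand-in for a tree
  trained on expert labels; the hook for loading a trained tree exists.
* Lobular region annotation must be supplied externally for real data; the
  package does not segment central veins or portal tracts.
* Strings fully inside a supplied vessel-lumen mask can be excluded, but
  no lumen mask is derived automatically.
* Spearman p-values use the t-approximation, inaccurate below n ≈ 10.
* CPA is an SHG analog, not a stained-section measurement.
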