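# Methods

`nfquant` quantifies neurofilament-positive (NF-positive) nerve profiles in
brightfield scans of immunohistochemically stained sections of the
biceps-tendon/labrum complex: DAB (3,3'-diaminobenzidine) marks nerve
profiles brown against a blue-purple haematoxylin counterstain. The package
has three layers: a measurement pipeline (tissue segmentation + object
detection), a group-statistics layer, and a synthetic-slide generator that
provides calibrated, ground-truthed inputs in place of cadaveric slides.

## Tissue/background separation

Brightfield scans have a near-white empty background and darker tissue. The
pipeline works at a reduced resolution (default 12.5% of the original,
area-average resampling) and proceeds:

1. **Quadtree tiling.** The working image is recursively quartered (canvas
   padded to a power of two; padding never enters a block) until each
   square's brightness SD is at or below `homogeneity_sd` (default 5.0 on
   the 8-bit scale) or the square reaches `min_block_side` (default 4 px).
   Brightness is the unweighted mean of R, G, B (luma weights are a config
   option). Homogeneous regions — above all the background — end up in
   large squares; textured tissue fragments into small ones.
2. **Brightness estimation.** Background brightness = median over the
   largest squares; tissue brightness = median over *all* squares, which is
   valid only when tissue squares are the majority — true for sections that
   fill most of the scan, and built into the generator's geometry. If the
   background estimate does not exceed the tissue estimate the input is
   flagged degenerate and a manual threshold is required.
3. **Midpoint threshold.** A pixel is tissue iff its brightness is below
   the midpoint of the two estimates.
4. **Enclosed-speck absorption.** 4-connected tissue components that do not
   touch the image border and occupy at most `enclosed_max_fraction`
   (default 0.1%) of the image are relabelled background. The limit is
   inclusive.
5. **Surface-tension-constrained growing.** Boundary pixels (those with a
   4-neighbour of the opposite label) adopt the majority label within a
   disc (radius 2, 3 iterations by default); ties keep the current label;
   interior pixels never change. A plain majority filter cannot guarantee a
   shrinking border, so the implementation enforces the contract directly:
   an iteration whose result would increase the 4-adjacency boundary length
   is discarded and relaxation stops. In practice the guard never fires on
   slide-like masks; it exists so the perimeter-non-increase property holds
   unconditionally.
6. **Synchronization.** The working mask is upscaled nearest-neighbour to
   full resolution using the same block partition as the downscaling, so
   each full-resolution pixel maps to exactly one working pixel.

Near-white pixels inside tissue (brightness >= `white_cutoff`, default 250)
are treated as unstained voids and excluded from other-tissue areas.

## Nerve-profile detection

Inside tissue-and-ROI masks at full resolution:

1. **Candidates** are pixels with blue below a threshold. The default
   `"auto"` threshold is Otsu's method on the masked blue values with a
   stain-presence guard: the two Otsu classes must differ in mean blue by
   at least `min_class_separation` (default 50 grey levels, about half the
   DAB-vs-haematoxylin blue gap). Without the guard, a slide containing no
   chromogen would have its counterstain noise split in half and flagged
   wholesale; with it, the no-stain case correctly yields an empty
   candidate set.
2. **Refinement** dilates candidates by a small disc (radius 2) and keeps
   pixels with R − B above `rb_diff_threshold` (default 30). DAB is
   red-dominant (R − B ≈ +70 in the generator's colour model) and
   haematoxylin blue-dominant (R − B ≈ −40), so the sign alone removes
   counterstain.
3. **Object formation**: morphological closing (disc 1) then opening
   (disc 1); 8-connected components; components whose minimal pairwise
   pixel distance is at most `merge_gap` (default 3 px, Euclidean between
   pixel centres) are merged — a documented stand-in for a neighbourhood
   criterion whose original operator is proprietary; components outside
   [`min_size`, `max_size`] = [4, 5000] px² are discarded.
4. **Assignment and measurement**: each object belongs to the ROI
   containing its (rounded) centroid; objects with centroid outside all
   ROIs are dropped and logged. Per ROI the pipeline reports the count,
   the object area (member pixels inside that ROI, so object + other-tissue
   area can never exceed the ROI's tissue area), the other-tissue area, and
   the mean object size (both "total size" readings are emitted since
   either convention is defensible).

Objects use 8-connectivity and background topology 4-connectivity,
consistently. None of the detection defaults comes from a published value;
all are configuration, logged into each run's provenance block.

## Group statistics

Counts from the four ROIs (I anterior superior labrum, II mid-portion at
the tendon origin, III posterior superior labrum, IV proximal tendon) are
compared as independent groups — deliberately reproducing the common
practice for this design; a mixed model honouring the repeated-measures
structure is out of scope and would be the statistically stricter choice.

* **Normality gate**: per-group Kolmogorov–Smirnov with the Lilliefors
  correction (mean and SD are estimated from the sample; the uncorrected
  KS null would be anticonservative), α = 0.05. Constant groups are
  degenerate: no test is run and the gate routes to the rank branch, which
  tolerates them.
* **Parametric branch**: one-way ANOVA, Tukey HSD over the six ROI pairs
  (studentized-range distribution; family-wise by construction).
* **Nonparametric branch**: tie-corrected Kruskal–Wallis H; Dunn's z per
  pair from pooled mean ranks with tie-corrected variance; two-sided p
  multiplied by 6 and clipped at 1 (Bonferroni, matching the convention of
  the desktop statistics packages this decision path mirrors; Holm is a
  config option). If every observation is identical, H is undefined and the
  result is reported as "no evidence" with all p = 1.
* **Normalization**: each specimen's counts are divided by that specimen's
  ROI I count and scaled to percent, making ROI I exactly 100 everywhere.
  Specimens with a zero reference count are excluded with a warning.
  Normalized tables carry float counts; the integer-count invariant applies
  to raw measurement tables only. Normalization is per-specimen (not on
  group means): that is what makes the shared specimen-level variation
  cancel and is the reading consistent with a ratio comparison.

## Synthetic slides and cohorts

The generator emulates only what the algorithm consumes:

* **Geometry**: a stylized arc-plus-stem section — the lower half of an
  annulus (outer radius 0.44 × min(height, width)) split into three equal
  sectors (ROI I left/anterior, II bottom/mid, III right/posterior) with a
  stem (ROI IV) descending from the arc bottom. The tissue region is the
  ROI union dilated by 3 px, hence contiguous and strictly containing every
  ROI. Exact anatomy is irrelevant to the algorithm; the arc is drawn large
  so that tissue squares dominate the quadtree (see brightness estimation).
  Images must be at least 256 × 256 for the bands to fit.
* **Colours** (config, not constants): background (245, 245, 245),
  counterstain (150, 140, 190), chromogen (120, 70, 50), vessels
  (210, 170, 190). These give chromogen a ~110 grey-level R − B margin over
  counterstain, the contrast the detector assumes.
* **Texture and noise**: a coarse counterstain texture (SD 10, constant
  over 8 px cells so it survives the 8× downscale) plus i.i.d. Gaussian
  pixel noise (SD 6) added everywhere and clipped to [0, 255].
* **Counts**: per-ROI object counts are rounded, zero-truncated Normals
  with the profile's (μ, σ). One standard-normal specimen factor is shared
  across the four ROIs with loading sqrt(ρ) (default ρ = 0.5; required for
  per-specimen normalization to behave like a ratio of correlated
  measurements). The shipped profile `"paper2017"` holds
  μ = (42.1, 33.7, 23.1, 33.8), σ = (15.0, 13.1, 7.3, 13.4) for ROI I–IV —
  the group means and SDs of the ten-specimen cadaveric cohort this package
  re-implements the analysis of. One slide represents one specimen (the
  sectioning protocol cut several sections per sample; whether the reported
  counts aggregate them is unstated, so the simplest reading is used).
* **Objects**: ellipses with radius 2.5–4.5 px, elongation up to 1.8
  (area-preserving split of the semi-axes), placed with a minimum centroid
  separation of 16 px — chosen so the worst-case gap between two true
  objects (16 − 2·4.5·√1.8 ≈ 3.9 px) exceeds the default merge gap of 3 px:
  distinct true objects are separable by construction. 70% of objects are
  seeded adjacent to one of 2–4 elliptical vessel profiles per ROI,
  mimicking the perivascular location of nerve profiles. An object that
  cannot be placed after 300 attempts is skipped; ground truth always
  records what was actually placed.

What the generator does **not** model: collagen fibre texture, polarized
light, scanner artefacts, stain gradients, out-of-focus blur, annotation
error. Passing tests therefore demonstrate correctness of the algorithmic
chain under the stated colour model, not robustness to real-slide
variability.

## Problem sizes, tolerances, numerical notes

* Count-recovery validation uses 40 slides of 1024 × 768 px; the
  tissue-overlap (Jaccard ≥ 0.95) contract is validated on 512 × 512
  slides. Below about 512 px the 8× nearest-neighbour synchronization
  staircase dominates the boundary error and the overlap contract is not
  claimed.
* Oracle-equivalence tests compare against brute-force re-implementations
  on ≤ 16 × 16 images or ≤ 20-value tables, exactly for integer/rank
  arithmetic and to 1e-9 for floating point.
* The cohort-level type-I error of the full decision path is checked by
  simulation (1000 equal-mean cohorts) against a ≤ 0.07 family-wise bound
  at α = 0.05.
* Determinism: all randomness flows through `numpy.random.default_rng`
  seeded explicitly; a cohort's specimen k derives its sub-seed from
  `SeedSequence([base_seed, k])`, so specimen k is identical regardless of
  cohort size. Re-running any command with the same seed reproduces
  byte-identical CSVs.
* Degenerate inputs are contracts, not crashes: inverted-contrast images
  raise with a manual-threshold instruction; empty ROI intersections raise
  a mismatch error; constant statistical groups route to the rank branch;
  an all-identical cohort reports "no evidence".

## Known limitations

* The original analysis ran in a proprietary object-based image analysis
  suite whose rule set (scale parameter, neighbourhood semantics, exact
  thresholds) is unpublished; every such gap is filled by a documented,
  configurable analogue (SD homogeneity criterion, merge-gap rule, midpoint
  threshold, guarded Otsu). Numerical agreement with the original software
  on real slides is therefore not claimed — recovery of the calibrated
  synthetic truth is.
* Areas are reported in px² only; the scanner's µm/px scale is unknown.
* ROIs are exchanged as indexed PNG masks, not polygons; whole-slide
  pyramidal formats and colour management are out of scope.
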