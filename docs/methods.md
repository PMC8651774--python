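# Methods

This note documents the models, conventions and numerical choices behind
`rbcbiophys`, what the synthetic data generator does and does not emulate,
and the known limitations. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## The measurement model

The package analyses paired micrographs of a red-blood-cell (RBC) monolayer
immobilized in an elastic gel, imaged before and after a vertical
compression that expands each cell laterally. Per cell, four descriptors are
computed:

* **mean diameter** = √(area/π). This is the device's printed definition and
  is implemented verbatim; note that for a disc of geometric diameter *d* it
  evaluates to *d*/2 (it is mathematically the equal-area-circle radius).
  All recovery checks therefore compare the measured descriptor against the
  same descriptor evaluated on true areas, never against the geometric
  diameter.
* **circularity** = 4π·area/perimeter², equal to 1 for a perfect circle.
* **axis ratio** = MaxFeret/MinFeret, the extreme caliper widths of the
  convex hull of the region's pixel *corners* (corner convention so a single
  pixel has a finite, 1-px footprint). Max Feret is the hull diameter;
  min Feret is the rotating-calipers minimal width over hull edges.
* **deformation index** Dr = √(S_d/S_ud), where S_ud and S_d are the pixel
  areas of the same cell before and after compression. Dr is unitless (the
  pixel scale cancels) and may fall below 1 for contracting cells.

Population statistics are the arithmetic means of these descriptors plus a
**distribution width** for each, defined as 100·SD/mean with the sample SD
(n−1) — the coefficient of variation, mirroring the hematology RDW
convention (plain SD is available via `width_mode="sd"`). The fixed
8-vector order is (diameter mean, diameter width, circularity mean,
circularity width, axis-ratio mean, axis-ratio width, Dr mean, Dr width).
Counts convert to concentration via field area × chamber depth (default
20 µm, the chip chamber height) ÷ dilution.

## Segmentation chain

Raw frame → 8-bit grayscale (ITU-R BT.601 weights) → percentile contrast
stretch (1st→0, 99th→255; monotone, so pixel ordering is preserved) → Otsu
threshold with cells-darker-than-background polarity (`invert` flips it;
fixed thresholds accepted) → hole filling (4-connected background, the dual
of the 8-connected foreground) → 8-connected component labeling.

Perimeter uses the Crofton 4-direction estimator, chosen so the circularity
of large rasterized discs approaches 1 (measured ≤ 3% error at radius
≥ 30 px); the chain-code estimator is available behind the same switch and
the choice is shared with all circularity computations. Regions touching
the border are flagged and excluded from morphometry and pairing by default.

**Stacked-cell removal.** Overlapping cells merge into one labeled blob and
are removed, not split. A region is rejected when area > k_area × median
area (k_area = 1.8, skipped below 3 regions), or solidity < 0.85, or
circularity < 0.6; each clause is individually switchable and all thresholds
are surfaced in `StackedCellParams`, since the appropriate setting depends
on the sample morphology. Two caveats are worth knowing: a blob of exactly
two overlapping equal discs sits near the rule's edge (circularity ≈ 0.62,
solidity ≈ 0.88), where only the area clause bites; and strongly irregular
single cells (schistocyte- or teardrop-like morphologies with circularity
sampled below 0.6) are legitimately caught by the shape clauses, so exact
count conservation holds for near-discocyte populations, not for extreme
poikilocytosis.

## Pre/post matching

Cells are gel-immobilized, so matching is a one-to-one assignment minimizing
total centroid distance (Hungarian algorithm) with a 3 µm displacement cap.
Areas are deliberately not a matching feature — they change under stress.
Dr is computed per matched cell (the per-cell scatter is the primary
output); unmatched and stacked-rejected cells are excluded from Dr
statistics.

## Synthetic scene generator

The generator defines the study conditions for every downstream test.

**Geometry.** Each cell boundary is the star-convex curve
r(θ) = s·R_ell(θ−φ)·(1 + ε·cos 5(θ−φ)): an ellipse with the sampled axis
ratio, randomly oriented, carrying a 5-lobed undulation whose amplitude ε is
solved by bisection so the boundary circularity matches the value sampled
from the class profile (ε = 0 when the target exceeds the ellipse's own
circularity). The radial scale s normalizes the enclosed area to πd²/4 for
the sampled geometric diameter d. Diameters are truncated-at-zero normals;
axis ratios are reflected about 1; circularity targets are clipped to
(0.2, 1].

**Stress.** Compression multiplies every boundary radius by a per-cell
dr ~ N(dr_mean, dr_sd), truncated positive (resampled, 100-try cap): the
area scales by dr² and the shape is preserved (isotropic in-plane
expansion). The healthy-class defaults are the device's printed stress
calibration — mean 1.194, SD 0.045 at the low setting and mean 1.241,
SD 0.033 at the high setting — and `stress="none"` fixes dr = 1. The class
profile carries both (low, high) parameter pairs; this is the package's
resolution of a single-profile/multi-level interface.

**Placement.** Cells land by dart-throwing with a disjointness margin of
1.05 × the sum of post-stress radii + 0.5 µm, so non-stacked cells stay
disjoint in both frames. Stacking events are linear rouleaux chains
(default 3 cells) with consecutive centres at 0.75 × the sum of the two
local boundary radii along the chain axis, which guarantees overlap in the
pre frame and deeper overlap in the post frame. The 3-cell default is both
the canonical rouleaux morphology and robustly rejectable (chain circularity
< 0.5); 2-cell clusters are configurable but sit near the rejection
thresholds, as noted above. An optional border keep-out margin
(`border_margin_um`) removes border-clipping ambiguity when exact counts
matter.

**Photometry.** Dark rim, brighter biconcave centre: attenuation below the
background rises quadratically from 30% of the rim depth at the centre to
full depth at the rim (background 210, rim depth 120 gray levels).
Overlapping cells combine by intensity minimum. A linear illumination ramp
(default 10% peak-to-peak) and additive Gaussian sensor noise (default
SD 3 gray levels) are applied before clamping to 8 bits. Because the rim is
always the darkest structure and the edge is sharp, any threshold between
rim and background captures an annulus whose hole-filled interior equals the
true footprint — which is why area recovery is robust to the exact
threshold.

**Defaults** (one field): 250 × 250 µm at 0.25 µm/px (4 px per µm, so a
7.5 µm cell spans 30 px — stable perimeter estimation), 150 cells, 5%
stacking. Determinism is strict: a single scene seed streams separate
sample/stress/placement/noise generators, and identical (config, seed) give
bit-identical images.

**Per-class profiles.** The six disease classes (healthy, megaloblastic
anemia, myelofibrosis, iron-deficiency anemia, TTP, thalassemia) and two
storage classes ship with synthetic defaults chosen once from standard
hematology morphology (macrocytes, teardrop cells, microcytes,
schistocytes, target cells, storage sphering/stiffening). They are
plausible, fully user-configurable, and *not* measured values; only the
healthy-class deformability pair is a printed calibration.

**What the generator does not emulate:** optical blur and defocus, shading
beyond a linear ramp, white cells, platelets and debris, chromatic effects,
cell motion between frames, and anisotropic deformation (an isotropy
assumption matching the area-based Dr readout). Tests passing on these
scenes therefore validate the computational chain, not robustness to every
real-world imaging artifact.

## Fused classifier

One sample = one field image + the 8-parameter vector. The image
contributes a 32-d embedding; the concatenated 40-d vector feeds fully
connected layers 40 → 64 → 20 → classes with inverted dropout (default
0.5), softmax cross-entropy, and Adam (default 1e-3, 200 epochs, batch 32 —
the original protocol leaves the optimizer open, so these are package
defaults and all surfaced). Features are standardized by training-split
mean/SD, stored with the model. Training runs stratified 90/10
development/validation cycles, re-shuffled each cycle, and reports per-cycle
validation accuracy; everything is deterministic given the config seed.

The image backbone is an *untrained* seeded convolutional filter bank
(8×7×7 stride 4, 16×3×3 + 2×2 mean pool, 32×3×3 + pool, global average
pool): a deterministic random-features embedding with no external weights.
A pretrained-AlexNet backbone is accepted in the config for API parity but
raises, since it would require downloaded weights. Consequence: the
embedding is sensitive to field texture and density but carries substantial
within-class scene variance, so at desk scale the discriminative power lives
mainly in the parameter vector; the three model variants (morphology
parameters only; + image; + image + mechanics) are all constructible from
one config switch, and the ablation property asserted on synthetic data is
monotonicity — adding the mechanical features does not reduce validation
accuracy, and carries the signal when classes differ only mechanically.

Inputs are center-cropped to exactly 0.1 mm × 0.1 mm, resized to 224 × 224,
scaled to [0, 1]. Augmentation (random 0–360° rotation with reflected
padding, crop jitter, flips) is available and seed-deterministic, off by
default at desk scale.

## Method-comparison statistics

* **Bland–Altman:** bias = mean difference, 95% LOA = bias ± 1.96·sample SD.
  The difference direction (device − comparator by default) and
  absolute-vs-percent mode are explicit parameters because comparator
  studies mix conventions (percent for relative morphology quantities,
  absolute for counts).
* **Passing–Bablok:** classical procedure — slope = median of pairwise
  slopes shifted by K (the count of slopes < −1), slopes of exactly −1
  excluded, identical points omitted, vertical pairs kept as ±∞ in the
  ordering; intercept = median(y − slope·x). CIs are the classical
  rank-based intervals, with the intercept CI evaluated at the slope CI
  bounds.
* **ROC:** empirical curve; trapezoid AUC (equal to the Mann–Whitney
  statistic); operating threshold by Youden's J with positives at
  score ≥ threshold; Clopper–Pearson CIs for sensitivity/specificity and a
  DeLong CI for the AUC (method names are carried in the output).
* **Mountain plot:** sorted differences with Hazen midpoint percentiles
  100·(i−0.5)/n, folded above 50 (→ 100 − percentile). The curve uses the
  midpoint convention; the reported 5th/95th summary percentiles use
  nearest-rank so they are observed differences, and the center is the
  median difference.

All four are cross-checked in the tests against independent brute-force
oracles (O(n²) slope enumeration, Mann–Whitney pair counting, hand-computed
LOA cases, the fold bound).

## Numerical choices and degenerate inputs

Truncated normals everywhere a negative draw would be unphysical, with a
documented 100-retry cap. Single-pixel regions define both Ferets as one
pixel. Constant images pass through contrast adjustment with a warning and
produce an empty mask with a warning at thresholding. Empty inputs raise
(`summarize`, `deformability_summary`) or return empty structures
(`match_cells`, `remove_stacked`) per the operation contracts. Ground-truth
boundary geometry uses 512-point polygons (256 during the ε bisection) —
area normalization is exact by construction and truth circularity is
accurate to ≲ 1e-3.

## Problem sizes used by the test and acceptance runs

Chosen as desk-scale defaults: deformability recovery uses 2,362 cells in
16 noise-free 250 µm fields at 0.25 µm/px; classifier checks use 6 classes
× 60 samples under 3 stratified 90/10 cycles; statistics oracles use the
small n the contracts state (12–100). The device's clinical headline
accuracies are not reproduced — they derive from patient data that is not
deposited — which is why validation rests on analytic values, generator
recovery, and oracle equivalence instead.
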