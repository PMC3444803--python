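# Methods

## Texture encoding

Each voxel of a registered 3D scalar image is encoded on the three
orthogonal planes through it (xy, xz, yz) with the same radius R, giving
three P-bit local binary pattern codes. The bit for neighbor p is 1 when
the neighbor value is **greater than or equal to** the center value; ties
therefore count as 1 and a perfectly flat image encodes to the all-ones
code 2^P − 1 everywhere. Neighbors sit at angles 2πp/P counter-clockwise
from the +first-axis direction of the plane; bit p carries weight 2^p.
The literature does not fix a single angular origin or bit order — any
consistent convention yields equivalent features up to a permutation of
histogram bins — so this one is frozen for reproducibility and is what the
tests and the skimage cross-check assume.

Two sampling modes exist. `circular_interpolated` (default, the standard
LBP_{P,R}) bilinearly interpolates off-grid samples; `square` takes the
eight surrounding grid offsets scaled by an integer radius, corresponding
to the classical 3×3-window picture of the operator. Radii are specified in
mm and divided by the in-plane voxel spacing, which must be isotropic
within the plane (a flag allows per-plane conversion on anisotropic grids).
Voxels whose neighborhood leaves the volume on any plane are *invalid* and
excluded from every histogram — padding would fabricate texture.

Numerics: bilinear samples are computed as nested lerps
(a + f·(b − a)), which is exact when the bracketing samples are equal, so
in-plane-constant regions always produce exact ties. Interpolated values
are compared at full float precision with no epsilon. Nearly-integer
sample offsets (|δ| < 1e−9, e.g. the axis-aligned neighbors of a circular
ring) are snapped to the grid so those samples are literal voxel values.

**Gray-scale invariance.** Codes depend only on the ordering (and exact
ties) of the compared values. With on-grid sampling (square mode) the codes
are therefore exactly invariant under any strictly increasing intensity
map. With interpolated sampling, interpolation commutes with *affine*
intensity maps only, so exact invariance holds for affine maps; smooth
nonlinear monotone maps (e.g. exp) can flip a bit where an interpolated
value and the center are nearly equal — empirically a sub-percent bit-flip
rate on smooth random fields. This is a property of interpolated LBP
itself, not of this implementation.

## Histogram features

Raw codes pass through the uniform-pattern table: every code with at most
two circular bitwise transitions (U ≤ 2) keeps its own bin, assigned in
ascending code order; all non-uniform codes share the final bin. For
P = 8 that is 58 + 1 = 59 bins (P(P−1)+3 in general). Histograms are
accumulated per atlas region over valid voxels — the *center* voxel's label
decides membership; neighbors may lie outside the region or mask, matching
a pipeline in which whole-head intensities exist beyond the parcellation.
The feature vector concatenates regions in ascending label order, planes in
the order xy, xz, yz, bins ascending; its length is
n_regions × 3 × 59 (177 / 20 532 / 33 630 for 1 / 116 / 190 regions).

Per-(region, plane) blocks are L1-normalized by default because region
sizes vary across subjects and parcellations; raw counts (whose block sums
equal the region's valid-voxel count — a conservation law the tests
enforce) are available with `normalize=False`. A region with no valid
voxels yields an all-zero block and a logged warning, never NaN.

## Volume handling

NIfTI images are reoriented to the closest canonical (RAS) axis order on
load, so plane names mean the same thing for every input; non-finite voxels
are a hard error unless explicitly zero-filled. Resampling between
isotropic grids keeps the world position of voxel (0,0,0), drops trailing
partial voxels rather than padding, and interpolates trilinearly (separable
per-axis lerp, exact on constants) or by nearest neighbor — the only mode
allowed for label volumes, so resampled atlases never contain invented
labels. Whether a given upstream registration tool's downsampling matches
pure trilinear interpolation is tool-specific; small third-decimal feature
differences are possible.

## Feature selection

Feature groups are merged iteratively: append group k's columns,
grid-search the linear-SVM penalty C (powers of two 2^−10 … 2^10, best
internal-CV accuracy, ties to the smallest C) by internal 10-fold CV on the
current training set, fit, rank columns by |w| (ties to the lower column
index), and keep the top ⌈n/2⌉. Groups flagged `whole_brain` are appended
without the drop — a whole-brain-mask histogram has only 177 columns and
halving it would discard most of an already-small descriptor. The flag is
explicit per group rather than inferred from a size threshold. The survivor
count obeys s_k = ⌈(s_{k−1} + n_k)/2⌉ exactly (no-drop groups add their
full size), which the tests assert as a closed form. C is re-searched at
every iteration since the merged matrix changes scale and dimension.

Selection is *always* fit inside the outer training split. The test suite
includes a leakage regression test: with shuffled labels, the nested
protocol stays at chance while running selection on the full data first
measurably inflates held-out accuracy.

## Classifiers and evaluation

The linear SVM is liblinear-backed (squared-hinge loss, primal solver,
tol 1e−6), deterministic given the data order; its decision is
sign(wᵀx + b). The baseline is 1-nearest-neighbor with Euclidean distance,
ties to the lower training-row index. No feature standardization is applied
beyond histogram normalization (an optional flag exists); classes are
handled as the two distinct values of the label vector.

The outer protocol partitions subjects into n_folds (default 10) balanced
folds by seeded shuffle (a stratified option exists behind a flag); each
fold is held out once and the pooled held-out predictions give the
accuracy, so the pooled accuracy equals the fold-size-weighted mean of
per-fold accuracies by construction. The same plan object can be reused
across models to make paired comparisons meaningful.

## Statistical tests

Permutation test: the full pipeline is re-run on k label-*permutations*
(class balance preserved, not i.i.d. relabelings), with
p = (#{e′ ≤ e} + 1)/(k + 1); ties count toward significance-destroying
evidence and the smallest attainable p is 1/(k+1). The default re-runs the
whole pipeline per replicate; a `reuse_C` fast path trains every fold at a
fixed C, which is what the acceptance runs use at k = 100 to keep 101
cross-validated evaluations cheap — on the strongly separable cohort the
chosen C barely matters because every inner accuracy saturates.

McNemar's test uses only the discordant counts b (first classifier right,
second wrong) and c (the reverse). The reported statistic is always the
continuity-corrected (|b−c|−1)²/(b+c); the p-value is the exact two-sided
binomial when b + c < 25 and the 1-df chi-square tail of that statistic
otherwise. With b = c = 0 the p-value is 1.

## Synthetic phantoms

The generator emulates the *premise* of the texture analysis — group
differences living in morphological texture, not first-order intensity —
with two texture families:

- `smoothed_noise`: Gaussian white noise smoothed with width
  σ = base_sigma + class_effect · class_id voxels (defaults 1.0 and 2.0, so
  the two classes have widths 1 and 3), variance-normalized so amplitude
  carries no signal;
- `fold_pattern`: a 3D sinusoidal folding lattice whose spatial frequency
  is base_freq · (1 + class_effect · class_id) (base 0.08 cycles/voxel),
  with random phases; `probability_mode` squashes values into [0, 1]
  through a logistic to emulate tissue probability maps.

Both add `noise_sd` white measurement noise (default 0.05). The mask is a
central ellipsoid with semi-axes 0.42 × shape; the atlas splits it into
n_regions contiguous slabs along the first axis. With class_effect = 0 the
two class-conditional distributions are identical by construction, giving
the null calibration used in the tests. All draws are pure functions of
(seed, class_id), with per-subject sub-seeds spawned deterministically.
Region timecourses are multivariate Gaussian with a block-constant target
correlation, drawn through the Cholesky factor.

What the phantoms do **not** model: real cortical anatomy and folding
geometry, registration error, intensity inhomogeneity, scanner artifacts,
and site effects. Passing the recovery tests shows the pipeline detects
texture-scale differences at realistic sample sizes; it does not certify
effect sizes on clinical data.

## Problem sizes in the test and acceptance runs

The packaged study conditions use 24³-voxel phantoms at 60 subjects/class
(whole-brain mask, P = 8, R = 1 mm) for the strong-effect recovery runs,
16³ phantoms at 20/class for the null calibration, 100 seeded replicates at
k = 49 for the null permutation-uniformity census, and 80-subject datasets
with 5 informative among 1024 noise columns (per-feature AUC ≈ 0.9) for the
selection-recovery census. These sizes were chosen once as the smallest
cohorts at which the expected behavior (near-ceiling separability of the
width-1-vs-3 smoothing contrast, binomial chance bands, ≥ 95 % planted
feature survival) is comfortably identifiable.

## Known limitations

- Exact monotone-map code invariance holds only for on-grid sampling (see
  above).
- P ≠ 8 is supported for correctness but not optimized; rotation-invariant
  LBP variants are out of scope.
- The iterative selector's grid search re-runs a full internal CV per
  candidate C per group, which dominates runtime for many large groups.
- Anisotropic inputs require either resampling to an isotropic grid or the
  explicit per-plane radius-conversion flag; in the latter case plane
  histograms are no longer strictly comparable across axes.
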