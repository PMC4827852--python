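# Methods

## Problem and pipeline

Whole-spine sagittal (or coronal) MR coverage is acquired as two or
three overlapping fields of view — cervical, thoracic, lumbar — that
differ essentially by patient-table translation.  `spinestitch`
registers and composites them from image content alone (no scanner
geometry metadata), in five stages: scale-space extrema detection,
sub-pixel keypoint localization and filtering, orientation assignment,
descriptor computation, and descriptor matching; a transform is then
fitted to the matched point pairs and the segments are blended onto one
canvas.  For multi-slice stacks the transform is estimated on the most
central slice only and applied unchanged to every slice, which assumes
the slices of one stack are mutually co-registered (true for a single
FSE acquisition, not necessarily across re-positioned acquisitions).

## Scale space and detection

The Gaussian scale space uses base blur σ₀ = 1.6 px, 3 scales per
octave (k = 2^(1/3)), s + 3 = 6 Gaussian levels per octave so every
scale has DoG neighbors above and below, an assumed input blur of
0.5 px, and as many octaves as keep the image at least 16 px per side.
No initial 2× upsampling is performed: spine matrices (420²–576²) are
large enough that the finest native octave already carries the relevant
detail.  Blurs are applied incrementally (σ_inc = √(σ_t² − σ_c²)) with
reflect-at-edge padding (preserves constants, avoids spurious border
extrema) and kernels truncated at 4σ (truncation error below 1e-4).

Candidates are strict extrema over all 26 neighbors; ties are rejected,
so flat regions yield nothing.  The 3-D quadratic refinement iterates
(at most 5 times, re-centering when an offset component exceeds 0.5)
and a candidate is dropped if its Hessian is singular or the iteration
leaves the pyramid.  The contrast gate |D(X̂)| ≥ 0.03 is applied to the
*interpolated* extremum value — the Taylor-model value at the refined
position — since the refined value is what the quadratic model says the
extremum actually is.  The DoG here is unnormalized (no k−1 or σ²
factor), which makes deep-octave responses weaker; one visible
consequence is that a Gaussian blob's extremum sits one scale level
below the blob's nominal σ rather than exactly at it.  The edge test
implements the curvature ratio with the true determinant
Dxx·Dyy − Dxy² and γ = 10, rejecting saddles (Det ≤ 0) outright.

## Orientations and descriptors

Gradients follow the raw central differences m = √(Δx² + Δy²),
θ = atan2(Δy, Δx) mapped to [0, 2π) (the factor-of-two in the
differences cancels in the angle and in the normalized descriptor).
The orientation histogram has 36 bins over a window of radius
3 × (1.5 σ) — the window multiple is applied to the 1.5 σ weighting
scale, the more generous of the two possible readings — with samples
weighted by a 1.5 σ Gaussian; the highest peak, and every other local
peak at ≥ 80% of it, yields an oriented keypoint, with parabolic
refinement over the three bins around each peak (10° bins alone are too
coarse for sub-pixel stitching).

The descriptor samples a 16×16-sample support (4 samples per spatial
cell, sample spacing proportional to the keypoint scale), rotates
coordinates and gradient angles into the keypoint frame, and
distributes Gaussian-weighted magnitudes trilinearly into 4×4 spatial
cells × 8 orientation bins = 128 values, normalized to unit length,
clipped at 0.2 and renormalized (clipping bounds the influence of any
single strong edge; without normalization, matching would be
illumination-sensitive).  The descriptor window's Gaussian weight uses
σ equal to half the window width: a literal 1.5 σ_kp weight over a
16 σ_kp-wide support would suppress everything but the central cells
and effectively discard the outer 12 histograms.

## Matching and robustness

Matching is exhaustive nearest-neighbor on Euclidean descriptor
distance, with three per-match filters, each of which can be disabled
to obtain raw nearest-distance matching:

- **ratio test**, default 0.7: in same-protocol stitching the overlap
  band is (up to noise) the *same image content*, so correct matches
  show nearest/second-nearest ratios well under 0.6, while repetitive
  anatomy — one vertebra's corner matched to another's — produces
  lookalike matches with ratios spread across 0.4–0.8.  Measured on the
  phantom, the conventional 0.8 threshold admits roughly 40% outliers,
  which is fatal for a median estimator that needs an inlier majority;
  0.7 restores a comfortable margin without losing correct matches.
- **mutual consistency**: B's nearest neighbor in A must be the same
  pair.
- **geometric consistency** (keypoint-level matching only): the two
  keypoints' scales may differ by at most a factor 1.3 and their
  orientations by at most 0.35 rad.  The stitching transform family is
  near-rigid (translation, or similarity with small rotation and scale),
  so true correspondences must preserve scale and orientation; each
  match is checked in isolation against fixed bounds — no sampling, no
  consensus estimation — so this is a model-family prior, not an
  outlier-consensus scheme such as RANSAC (which is deliberately not
  implemented).

The translation estimate is the component-wise median of the matched
displacement vectors: exact on consistent pairs, robust to any outlier
minority.  A least-squares similarity fit (rotation + isotropic scale)
is available for tilted acquisitions.  In sequential stitching, each
pairwise transform is estimated between *adjacent raw segments* and
composed into the mosaic frame: the overlap band lies entirely within
both raw segments, whereas matching against the whole grown mosaic
roughly doubles the pool of non-overlap keypoints and with it the false
matches.  The point pairs actually used are recorded in mosaic
coordinates, so a manual-mode replay of the automatic pairs reproduces
the canvas bit for bit.

## Compositing

The canvas is the bounding box of the reference segment and the
transformed segment; resampling is bilinear, with sampling coordinates
given a 1e-6 px tolerance at the borders and near-integer bounding-box
edges snapped (a translation estimated a micro-pixel off an integer
must not grow the canvas by a spurious row).  Overlaps are combined by
feather blending — each source weighted by its distance to its own
valid-data boundary, weights normalized to sum to 1 — which hides the
seam intensity steps that per-segment coil sensitivities produce;
`average` and `overwrite` modes exist for comparison.  No inter-segment
gain correction is applied: inputs are assumed on a shared [0, 1]
scale (a documented limitation).  Pixels covered by no segment are
background 0.  The central-slice index for even stack sizes is the
lower middle, floor((N−1)/2).

## Intensity conventions

Stacks read from disk are min–max normalized to [0, 1] jointly over the
stack, so slices stay mutually consistent; a constant image maps to all
zeros.  This normalization is what gives the absolute 0.03 contrast
threshold its meaning.  DICOM reading applies rescale slope/intercept
before normalization and orders slices by the image-position projection
onto the slice normal, falling back to instance number; DICOM
windowing is deliberately ignored (window settings are display advice,
not signal).

## Agreement statistics

For a reference/test pair the package reports NMSE — defined as
Σ(ref − test)² / Σ ref², the most common of the several conventions
that share the name, and stated in every report because the choice
changes the scale of the number — Pearson's r with its p-value, R² as
the squared correlation (equal to the coefficient of determination of
the least-squares line), and Bland–Altman mean difference, sample SD
(n − 1), limits of agreement at mean ± 1.96 SD, and the fraction of
differences outside the limits.  Slicewise comparison adds a pooled
report over per-slice mean intensities.  Comparisons can be restricted
to a valid-data mask so background padding does not inflate agreement.

## Synthetic phantom

The generator emulates a sagittal whole-spine acquisition: a laterally
curved column of bright vertebral bodies (default 12) separated by
darker discs, a spinal-canal band, dark background.  Three design
choices matter for realism *as seen by a feature matcher*, and were
fixed once:

- vertebral bodies grow head-to-foot (pitch scaled linearly 0.7→1.3),
  as in real anatomy; this also keeps the column aperiodic,
- structures carry spatially correlated texture (white noise smoothed
  at 1.5 px and 4 px correlation lengths, mixed, SD 0.12 ≈ 12%
  intensity — the order of marrow/soft-tissue heterogeneity in T2 FSE),
- each vertebra gets a small random brightness offset of its own.

A piecewise-constant periodic phantom is *not* an adequate stand-in:
its vertebrae are interchangeable to a descriptor, which makes matching
degenerate in a way real spine images are not.

`split_overlapping` cuts the phantom into vertical bands sharing
exactly `overlap_px` rows (default 56), with optional integer lateral
jitter, per-segment multiplicative gain (coil-sensitivity-like, drawn
once per segment) and per-pixel additive Gaussian noise (thermal-like,
default 0.01 SD in the simulation CLI); the true inter-segment
translations are recorded.  What the phantom does **not** model: real
MR contrast physics, susceptibility and wrap artifacts, patient motion
between acquisitions, inter-segment rotation, through-plane anatomy
changes, and intensity non-uniformity beyond a global per-segment gain.
Passing the phantom study therefore demonstrates the pipeline's
geometric correctness and noise robustness, not clinical performance on
scanner data.

## Numerical choices and degenerate inputs

- Strict inequalities for extrema; plateau ties yield no keypoints.
- Singular refinement Hessians, out-of-bounds iterations, and empty
  orientation windows drop the candidate rather than guessing.
- All-zero (degenerate) descriptors are excluded from matching;
  distance ties break toward the lower index for determinism.
- Keypoint lists are sorted by (y, x, σ, orientation); every stage is a
  pure function of its inputs and seeds, so identical configurations
  reproduce bit-identical outputs.
- Problem sizes used in the shipped study: a 700×256 phantom, three
  segments of ≈ 271 rows, ten seeded noisy splits plus one noise-free
  split — small enough to run the whole study in seconds while leaving
  every octave of the pyramid populated.

## Known limitations

No mismatch-correction stage (RANSAC or distance-weighted correction)
is implemented — the per-match filters above are the only outlier
defense, and a majority of false matches would still corrupt the
median.  The transform family excludes deformation and through-plane
motion; stitching is strictly 2-D per slice.  Multi-frame/enhanced
DICOM is not supported.  JPEG output is lossy and documented as such.
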