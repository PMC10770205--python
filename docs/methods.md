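# Methods

This note documents the models, parameter choices, numerical details and
limitations of `dsareg`. It is the design record a maintainer should read
before changing defaults.

## Problem setting and assumptions

Pre- and post-thrombectomy DSA series of the same view (AP or lateral) are
assumed to be related by a *global* planar transform. The true mapping is a
projection of 3D patient/C-arm motion and is not exactly planar; the working
assumption is that a scale-aware linear transform captures the clinically
relevant part of the misalignment, and that residual non-rigid effects are
treated as noise. Inputs are already-subtracted series (vessels dark on a
bright background); no motion correction between frames of one series is
attempted.

Intensities are min-max normalized per sequence to [0, 1]. A constant
sequence has no meaningful rescale and maps to all zeros — a documented
degenerate case, not an error. Coordinates are 0-based `(x, y)` =
(column, row) with the origin at the top-left pixel; sub-pixel positions are
real-valued. The minimum intensity projection uses all frames by default;
a half-open frame range can restrict it to a contrast phase, but no
bolus-phase selection is claimed or performed by default.

## Transform family and fitting

The family translation ⊂ rigid ⊂ similarity ⊂ affine ⊂ projective is fitted
to point correspondences by least squares on the sum of squared Euclidean
transfer errors:

* translation — mean displacement (closed form);
* rigid / similarity — Procrustes/Umeyama closed form; the optimal rotation
  is constrained to determinant +1 because projections of one view never
  mirror; a mirror-only correspondence set yields a degeneracy error rather
  than a reflection;
* affine — linear least squares;
* projective — normalized (Hartley) DLT, then Levenberg–Marquardt refinement
  of the *geometric* error, started from both the DLT and the affine
  solutions and keeping the better optimum. Seeding from the affine fit
  guarantees the projective objective never exceeds the affine one, so the
  nesting inequality holds numerically and not just in theory.

Stored matrices map moving (pre-EVT) points onto fixed (post-EVT) points.

Two residual statistics are reported. `mean_residual` is the arithmetic
mean of per-point Euclidean errors — the "average residual error" used for
validity decisions and distribution plots. `rms_residual` is the root of
the minimized objective. Monotonicity along the nested family is guaranteed
only for the RMS (each family contains the previous, so the minimized
objective cannot grow); the arithmetic mean of norms is *not* the minimized
functional and can increase slightly between adjacent families on noisy
data (observed in roughly one set in five, worst case below 0.1 px at 2 px
noise). Invariant tests therefore assert RMS monotonicity.

The transformation-type assessment fits all five types to every
correspondence set with at least 6 points; smaller sets are excluded because
few-point fits of high-dof transforms say nothing about alignment quality
(a projective transform interpolates any 4 points exactly). Residuals are
in-sample: the assessment asks which family can *represent* the observed
alignment, not how it generalizes.

`warp_image` uses inverse mapping with bilinear interpolation;
out-of-domain pixels take the background value 1.0 (no vessel).

## Landmark detection

The detector regresses one heatmap per landmark (ICA terminus, M1 segment)
from a minIP. Architecture: a convolutional encoder–decoder with skip
connections — per level two 3×3 conv + ReLU pairs, 2×2 max pooling down,
nearest-neighbour upsampling + skip concatenation up, a 1×1 conv head and a
per-pixel sigmoid. Channel widths double per level. Defaults: depth 4 /
base 16 channels at 512 px inputs; tests and the scaled-down training runs
use depth 3 / base 8 at 128 px. The network and its backpropagation are
implemented directly on numpy arrays (im2col + GEMM convolutions, float32),
with Adam as the optimizer; gradients are verified against central finite
differences in the test suite.

The sigmoid bounds each output pixel to (0, 1) but does not make the map a
distribution, so before a divergence is evaluated each predicted map is
clamped at ε = 1e-12 and normalized to sum to 1 (a per-pixel softmax is the
documented alternative; normalization of the sigmoid map was chosen because
it preserves the bounded per-pixel interpretation). Targets are isotropic
Gaussians centred on the annotation, normalized to sum to exactly 1;
`target_sigma` defaults to 4 px at 512 px images. Losses: KL(target‖pred)
or Jensen–Shannon divergence; JS is symmetric and bounded by ln 2.
The KL gradient with respect to the logits reduces analytically to
`-t(1-s) + s(1-s)/Σs`, which is what the backward pass implements.

Decoding: `argmax` returns the integer position of the maximum (ties broken
toward the lowest row, then the lowest column, for determinism);
`center_of_mass` returns the probability-weighted mean over the full map and
is sub-pixel. Training/validation splits are always made at the source-id
level so the pre and post images of one subject never straddle a split; a
3-fold cross-validation helper applies the same rule. The checkpoint kept
is the epoch with the lowest *median* validation centre-of-mass error
(median rather than mean: early training can place one landmark far off
while the other is already accurate).

Training runs in this repository are deliberately small (200 images of
128×128, ≤ 30 epochs, minutes on one CPU). They demonstrate that the
heatmap formulation learns the landmark geometry of the simulator; they say
nothing about clinical-scale performance, which would require the original
registry-scale training data.

## Feature-based registration

Images are rescaled to 8-bit before keypoint detection (the detector
implementations operate on integer intensities). SIFT runs without initial
2× upsampling: synthetic and clinical vessels are several pixels wide, so
the extra octave only costs runtime. ORB keeps its 500-keypoint budget.
Matching is nearest-neighbour in descriptor space (Euclidean for SIFT,
Hamming for ORB) with mutual cross-check and Lowe ratio 0.75.

Pooling concatenates the selected sources (SIFT, ORB, landmarks); pairs
identical on both sides within 0.5 px across sources collapse to one entry
so a junction found by two detectors does not vote twice. Landmark
correspondences enter unweighted.

Robust estimation is RANSAC over minimal samples (2 points for similarity),
inlier threshold 3 px, up to 2000 iterations with adaptive early stopping at
99.9% confidence, near-coincident samples (< 1 px apart) rejected, followed
by a least-squares refit on the final consensus and a recomputed inlier
mask. Fewer than 5 final inliers means *no solution*. All draws come from a
seeded generator; identical inputs and seed give identical output.

Validity: the mean Euclidean error of the estimated transform on reference
correspondences, compared to 10 px. "Greater than 10 px" reads strictly —
exactly 10.0 px is valid — with a 1e-9 guard so floating-point round-off
cannot flip the boundary. Without reference annotations the result is
reported as a third state, `unverified`, and excluded from success-rate
denominators.

## Synthetic data generator

The simulator provides the study conditions for every test:

* **Vessel tree** — recursive bifurcation from a root in the upper-central
  region (the ICA terminus; its first child is the M1 node), branch angle
  55° ± 12° jitter, segment length 0.22·H decaying by 0.72 per level,
  radius 6 px decaying by 0.8 per level (jitter small enough that radii
  strictly decrease), depth 6 at 512 px. All nodes are clamped inside the
  field of view.
* **Rendering** — edges are drawn as tubes with a flat dark core and a
  cosine falloff over one pixel (anti-aliasing chosen so SIFT/ORB find
  stable gradients); vessel contrast 0.8 below the background of 1.0. The
  contrast front advances with root-path distance so frame t darkens only
  edges within (t+1)/T of the maximum distance; the noise-free minIP
  therefore equals the full-tree rendering exactly. Per-frame Gaussian
  noise (default sd 0.02) is added and clipped to [0, 1].
* **Pairs** — the post image renders the full tree warped by a similarity
  transform sampled within |rotation| ≤ 15°, scale 0.9–1.1, |translation| ≤
  50 px (about the image centre); tube radii scale with the transform. The
  pre image renders the tree with ≈ 20% of edges removed from subtrees
  *distal to M1*, so both landmarks remain visible pre-treatment, as the
  landmark detector must see them in both phases. Ground-truth transform,
  landmarks and removal fraction are recorded; landmark pairs satisfy the
  recorded transform to 1e-9 by construction.
* **Reference correspondences** — 8 tree nodes (always including both
  landmarks) mapped through the true transform stand in for manual
  annotations when cohorts are scored.

Everything is a pure function of seed and configuration; cohort pair i uses
seed + i and the manifest records all ground truth.

What the simulator does **not** model: hemodynamics, 3D-to-2D cone-beam
geometry, in-series patient motion, structured DSA artifacts (quantum
mottle, burned-in text, mask misregistration), and anatomical variability
beyond a randomized bifurcation tree. Passing tests on this data shows the
pipeline's machinery is correct and self-consistent under known global
transforms — not that clinical success rates transfer.

## Problem sizes and tolerances

Test and acceptance runs use sizes chosen to keep the full suite in the
minutes range on one CPU: 100 trials per transform type for exact recovery
(tolerance 1e-6), 30 noisy 8-point sets for nesting (1e-6 on RMS), 20
instances against the brute-force similarity minimizer (1e-6 on the
objective; the oracle is a dense scale × angle grid with closed-form
translation, polished by Nelder–Mead), 100 seeded 20-point RANSAC instances
with 30% outliers (success: 0.01 scale / 0.5° / 0.5 px, ≥ 99 required),
a 50-pair cohort at 512 px for end-to-end evaluation (success rate ≥ 0.9,
median valid-solution error ≤ 3 px — bounds locked from a pilot run and
kept as regression bounds), and 200 images / ≤ 30 epochs for landmark
training (median validation centre-of-mass error < 8 px). The
warp-and-compare check of the generator uses the vessel-interior mask and a
0.01 mean-absolute-difference bound: the residual there is bilinear
interpolation error at the anti-aliased tube edges, which exceeds
quantization (1/255) by construction.

## Known limitations

* No deformable registration: the global-transform assumption is the
  method's scope, not a claim that cerebral DSA contains no non-rigid
  motion.
* No intensity-based refinement stage; image-based similarity metrics were
  not found to improve point-based solutions in this setting.
* The landmark detector ships untrained; clinical use requires training on
  real annotated series.
* DICOM support reads pixel data, frame count and pixel spacing only.
* RANSAC hypothesis sampling, the 3 px inlier threshold, the matching
  filters, and pooling-then-RANSAC for combined SIFT+ORB are this package's
  documented choices where the method description leaves them open.
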