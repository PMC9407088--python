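# Methods

## Model and assumptions

`fmritemplate` builds a subject-specific 3D fMRI reference volume by
registering and fusing the subject's own 4D time series, one z-layer at a
time. The underlying model is deliberately planar: within a layer, the
apparent motion between two time points is a 2D projective transform of the
pixel grid (homography by default; affine and rigid minimal models are
available via `--model` for the physically common case of small in-plane
head rotation/translation). Through-plane motion, spin-history effects and
BOLD signal dynamics are *not* modelled — frames whose motion exceeds a
limit are excluded rather than corrected, and anything needing resampling
in z is assumed to have been handled upstream by standard realignment
tools.

Registration is *sequential*: transforms are estimated between adjacent
frames (i, i+1) and chained back to the first retained frame,
cumulative(i) = T₁·T₂⋯Tᵢ. The justification is empirical and is asserted
by the test suite: on a drifting sequence, adjacent frames share more
matchable keypoints than (frame 0, frame i) pairs, so each estimated link
is more reliable than a direct long-range match, at the price of
accumulating small errors. The drift test bounds that accumulation:
20 chained links at ≈0.2 px per-link accuracy stay under 1 px of
cumulative corner error.

## Pipeline stages and parameters

**Scale space.** Gaussian pyramid with σ₀ = 1.6, s = 3 intervals per
octave (k = 2^(1/3), s+3 levels per octave), octave count
⌊log₂ min(w, h)⌋ − 2, reflect boundary handling, incremental blurring so
level j of octave o carries absolute blur σ₀·2^o·k^j. fMRI slices are
small, so no initial doubling is performed by default; `upsample=True`
(CLI `--upsample`) prepends a 2× bilinear octave and roughly doubles the
keypoint yield on 64–96 px slices, with detected coordinates reported in
the original grid. DoG levels are exact differences of adjacent Gaussian
levels.

**Keypoints.** Strict 26-neighbour extrema (ties discard plateaus) of
interior DoG levels, at least 5 px from the border. Sub-pixel refinement
solves the 3D quadratic Taylor offset with central differences; an offset
component beyond 0.5 moves the integer centre and re-solves (≤5 attempts).
Rejection: singular Hessian, non-convergence, interpolated |D| below the
contrast threshold (0.03 on min-max-normalized intensities), or a
principal-curvature ratio Tr²/Det ≥ (r+1)²/r with r = 10. Orientation is
the parabolic-interpolated peak of a 36-bin (10°) gradient-direction
histogram over a 3σ disc, magnitude-weighted with a 1.5σ Gaussian falloff;
exactly one orientation is assigned per keypoint (no secondary peaks).
Slices are min-max normalized to [0, 1] for detection only; fusion always
operates on original intensities.

**Descriptor.** 136-dimensional GLOH: log-polar spatial grid of 17 bins —
an undivided central disc plus two annuli of 8 sectors, ring radii 6/11/15
px scaled by σ/σ₀ so the support is scale-covariant — each holding an
8-bin histogram of gradient orientation relative to the keypoint's
dominant direction. Samples are soft-assigned trilinearly to adjacent
radial rings, angular sectors and orientation bins (the centre disc
absorbs its two sector shares undivided). Vectors are L2-normalized,
clipped at 0.2, renormalized; a zero-gradient window yields an all-zero
vector flagged as featureless. No PCA step is applied: 136 is the final
dimensionality.

**Matching.** Exhaustive Euclidean search; accept when
nearest/second-nearest < 0.9; one-to-one by keeping the closest claim per
reference keypoint (ties to the lower moving index). The per-pair
similarity statistic is 100·matches/min(n_ref, n_mov), reported to two
decimals. With the acceptance rule fixed, match counts are monotone
non-decreasing in the threshold.

**RANSAC.** m = 4 sampled pairs per homography hypothesis (3 affine,
2 rigid), non-collinearity enforced by a triangle-area test with tolerance
1e−6 × bounding-box², transfer-error threshold TR = 2 px, confidence
p = 0.995, adaptive bound k = log(1−p)/log(1−wᵐ) re-evaluated at every
consensus improvement, hard cap 2000 iterations, early exit when the
consensus reaches 80% of the matches. The final model is refitted by
normalized DLT least squares on the consensus set and kept only if support
does not shrink. Success requires at least m + 2 supporting inliers: a
minimal sample fits itself exactly, so bare-m support carries no evidence
and would make fully contaminated match sets "succeed". All sampling flows
from a caller-supplied seed; results are bit-reproducible.

**Fusion.** Three rules over the warped frames and their validity masks
(inverse bilinear warping; out-of-frame pixels carry mask 0 and never
contribute). `weighted` is the gradual-in/gradual-out rule: across the
overlap of a pair, weights ramp linearly along x between the overlap
bounds, ω₁ = (x₂−xᵢ)/(x₂−x₁), ω₂ = 1−ω₁ (a single-column overlap
degenerates to ½/½). That rule is defined for *pairs*, so sequences fold
in temporal order, F ← weighted(F, frame_i). Registered same-size fMRI
slices overlap almost fully, which makes the x-ramp weighting asymmetric
and order-dependent; the `mean` method (mask-weighted per-pixel average of
all frames in one pass) is the statistically symmetric alternative and the
recommended default when temporal-order semantics are not required.
`direct` is the plain pairwise average. All three are convex: fused values
stay within the contributing frames' min/max envelope, and averaging K
noisy frames shrinks independent noise by √K.

**Preprocessing.** The first n_discard frames (default 4, the usual
equilibration allowance) are dropped with frame-id bookkeeping. Motion
scrubbing uses a 6-column table (3 translations mm, 3 rotations deg; one
row per frame) with limits 2 mm / 2° per axis, or — when no table exists —
a data proxy: a frame is dropped when its mean absolute difference to the
previous retained frame exceeds median + k_mad·MAD (k_mad = 5, raw MAD) of
all consecutive-frame differences.

**Metrics.** MSE; NCC as the Pearson correlation of masked intensities
(error on zero variance); MI over a 32×32 joint histogram, each image
min-max binned over the evaluation mask, natural log; NMI =
(H(a)+H(b))/H(a,b), giving 2 for identical and →1 for independent images.
These definitions are fixed so reported numbers are comparable across
runs; `evaluate` on a 4D series against a 3D reference prints the mean of
each per-frame metric.

## Synthetic data

The phantom generator is the package's test bed and models exactly what
the pipeline assumes: a brain-like ellipse filled with Gaussian blobs of
mixed polarity on a jittered 5 px grid (σ 1.6–2.4 px — squarely inside the
detector's usable scale range) over a smooth ringed background. Animation
applies a per-frame in-plane similarity transform (uniform random-walk
steps, defaults ±1 px translation and ±1° rotation per frame — small
continuous drift of the kind head motion produces within a run), additive
Gaussian noise (default σ = 0.02 on the [0, 1] scale), optional decaying
intensity drift on the first n_unstable frames (emulating
pre-equilibrium signal), and optional large intensity jumps on designated
outlier frames (emulating motion spikes for the scrubbing proxy). All
ground-truth transforms are recorded in exactly the convention the
pipeline estimates (frame i → frame 0), so parameter recovery is scored
directly.

What the phantom does *not* emulate: through-plane motion, BOLD dynamics,
scanner drift/spikes beyond the injected ones, partial-volume effects, and
anatomical variation. Passing tests therefore demonstrate the geometric
and statistical correctness of the machinery on data obeying its own
motion model, not clinical performance on real acquisitions.

## Numerical choices and degenerate inputs

- Homography fitting uses Hartley-normalized DLT (zero-mean, √2 RMS);
  exact interpolation at 4 non-degenerate pairs, total least squares
  beyond.
- Composition order is fixed by the group-sum test: chained translations
  must add; cumulative(i) left-multiplies earlier pairwise maps.
- Warping is inverse bilinear sampling; a point mapped to the line at
  infinity (|w| < 1e−12) gets infinite transfer error and can never be an
  inlier.
- Constant slices normalize to all-zero, detect nothing, and — as blank
  frames — are flagged and excluded rather than aborting the layer; the
  layer only fails when *every* adjacent pair fails.
- NaNs in input files are an error by default (`nan="zero"` opts into
  zero-filling) because silent NaNs corrupt gradients.
- Keypoints are sorted by (y, x, σ) and every stochastic step is seeded,
  so identical inputs and seeds give bit-identical templates.

## Problem sizes used in the checks

The default test scale is 64×64 slices with 4–20 frames, and the
shape-preservation check runs the full pipeline at the native 96×96
in-plane size with 2 layers and 6 frames; layer count scales the work
linearly, so these sizes exercise every code path while keeping the suite
fast. The keypoint-richness contract of the generator (≥50 keypoints per
slice) is asserted at 96×96 with the upsample octave, the configuration
intended for slices this small; 64×64 layers assert a proportionally
scaled smoke bound.

## Known limitations

- The planar model cannot represent through-plane rotation; its residuals
  surface as slightly blurred fused layers rather than errors.
- Sequential chaining accumulates error linearly in the worst case; the
  adjacent-similarity advantage usually more than compensates, but very
  long runs (hundreds of frames) with weak texture would benefit from
  periodic anchor frames, which are not implemented.
- The gradual-in/gradual-out rule's x-ramp is a mosaicking heuristic; for
  fully overlapping registered slices the `mean` method is statistically
  preferable and provided as an option.
- Excluding a frame for motion also excludes it as a registration anchor;
  a frame immediately after a blank/failed frame is conservatively
  excluded too, since its only link runs through the failure.
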