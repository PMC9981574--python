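# Methods

This note records the models, parameter choices and numerical decisions
behind `daphtrack`, and what its synthetic-data experiments do and do
not demonstrate about real flow-cell video.

## Imaging model and background subtraction

The device scenario is a backlit flow cell filmed from a fixed camera:
the scene is static except for the animals and slowly drifting
particles, and illumination renders the animals dark on a light field.
The background estimate is the per-pixel arithmetic mean over a
trailing window of `fps x window_s` frames (default 15 fps x 20 s =
300 frames). The window keeps rolling after it first fills; a freeze
option exists because a fixed background is equally defensible when
illumination is stable, but rolling is the default since it adapts to
slow drift. No detections are produced during warm-up, so every
downstream statistic starts 20 s into the video.

Subtraction is the *absolute* difference, making the detector agnostic
to contrast polarity. The difference image is offset-invariant: adding
a constant to both frame and background leaves it unchanged.

## Automatic thresholding

Binarization uses scalar 2-means: Lloyd iterations on the difference
image's pixel values with k = 2, threshold = midpoint of the two
cluster means. Initialization is deterministic at the min and max pixel
values rather than random; on every input with genuine two-cluster
structure that we test, this converges to the exhaustive-scan optimal
1-D 2-means cut (the tests verify this against a brute-force oracle).
A seeded random initialization is available for fidelity to classical
k-means. Convergence: unchanged assignments, |Δμ| < 1e-6, or 100
iterations. An all-equal input is degenerate: the threshold equals that
value and the strict `>` binarization yields an empty mask.

Lloyd's algorithm is *not* globally optimal on structureless (e.g.
uniform) pixel sets; the oracle-equivalence tests therefore draw inputs
with separated modes, which is also the regime the thresholder sees in
practice (sensor noise near zero, object pixels far above it).

Connected components use 8-connectivity with a minimum area of 4 px to
suppress single-pixel noise; neither choice has a published standard
for this assay, so both are configuration options. Boxes follow the
half-open convention [x, x+w) x [y, y+h), 0-based, everywhere in
memory; the MOT-Challenge file dialect (1-based frames/ids) is
translated only at I/O.

## Patch classification

Candidates are classified from an 8x8 area-averaged resize of their
bounding-box crop, normalized to [0, 1] so the features are
illumination-scale invariant, then mapped to 64 Sobel gradient
magnitudes (3x3 kernels, replicated borders). Magnitudes were chosen
over signed Gx‖Gy concatenation for rotation robustness; the 128-dim
signed variant is available (`feature_set="xy"`). Defaults: random
forest with 100 trees, Gini impurity, sqrt(p) features per split; or
RBF-SVM with C = 1. The decision threshold on the Daphnia score is 0.5.
Confusion metrics use the standard definitions (accuracy, recall,
precision, F1 = harmonic mean of precision and recall), with undefined
ratios reported as `None` rather than 0.

## Tracking

The tracker is SORT with one modification: the association similarity
mixes bounding-box IOU with a normalized centroid distance,

    C_ij = (1 - lambda) * max(0, (max_d - d_ij) / max_d) + lambda * IOU_ij,

because small, fast animals often leave zero box overlap between
consecutive frames, where pure-IOU association fails. The distance term
is clamped at zero so C_ij stays in [0, 1] (the raw expression would go
negative beyond max_d). With lambda = 1 the tracker reduces to vanilla
IOU-SORT; with lambda = 0 it is a pure gated nearest-centroid tracker.

Kalman state and noise follow the public SORT convention: state
[u, v, s, r, du, dv, ds] with constant-velocity transition, measurement
[u, v, s, r] from the detection box, R = diag(1, 1, 10, 10),
P0 = diag(10, 10, 10, 10, 1e4, 1e4, 1e4),
Q = diag(1, 1, 1, 1, 0.01, 0.01, 1e-4); the covariance update uses the
Joseph form to preserve symmetry/positive-definiteness, and the scale
component is floored at 1e-3.

Lifecycle defaults (none published for this assay): lambda = 0.5,
max_d = 10 % of the frame diagonal, match gate c_min = 0.3, max_age = 5
frames of coasting, min_hits = 2 before emission — with the usual SORT
waiver of min_hits during the first frames so short videos are not
truncated at the start. Matched tracks emit the *detection* box (not
the filtered state), which keeps behavioural statistics anchored to
measurements. Track ids are never reused.

## Evaluation metrics

CLEAR MOT: per-frame matching keeps the previous frame's
correspondences while their IOU holds at the gate (default 0.5),
resolves the rest by maximum-total-IOU assignment, and accumulates
FN/FP/ID-switch events; MOTA = 100(1 - (FN+FP+IDs)/num_gt), MOTP =
mean matched IOU x 100. Identity metrics match whole trajectories
one-to-one (dummy-padded Hungarian on frame-level disagreement counts),
giving IDTP/IDFP/IDFN and IDP/IDR/IDF1. Small scenarios are verified
against exhaustive enumeration over all trajectory pairings.

## Behaviour statistics

Displacement is the Euclidean distance between an animal's centroids in
consecutive frames. A coasting gap of g frames contributes, by default,
g equal displacements of distance/g, keeping per-frame units comparable
(a skip mode records the single raw distance instead). "Stationary"
requires a tolerance: epsilon = 0.5 px/frame, a sub-pixel jitter floor,
since centroid estimates fluctuate by fractions of a pixel on a
motionless body. An animal is removed (counted immobile) when it shows
a run of >= 20 s x fps consecutive displacements all <= epsilon.
Per-20-s interval means are the unit for time-resolved analysis;
repeated-measures modelling of those tables is left to standard
statistics packages. "Radius of activity" has no standard definition;
the default is the maximum distance from the trajectory's
centre-of-mass, with a bounding-circle alternative, both flagged as
interpretations. Distances are in pixels (optionally scaled by
mm-per-px).

## Dose-response fitting

Immobility counts per concentration feed a two-parameter log-logistic
model, P(immobile | c) = 1/(1 + (EC50/c)^slope), fitted by maximum
binomial likelihood in (log EC50, log slope) with L-BFGS-B, bounds
log-slope in [log 0.05, log 30] and log-EC50 within 5 nats of the
tested range, and fixed starting values (EC50 at the geometric mean of
the concentrations bracketing the 50 % crossing; slope 1) — so the fit
is deterministic. Controls (c = 0) do not enter the likelihood. A
response that never crosses 50 % is refused rather than silently
extrapolated. Confidence intervals come from a seeded parametric
bootstrap; a probit link is available. This estimator replaces the
closed commercial program used for the original assays, whose internal
method is undocumented; log-logistic-vs-probit makes little difference
on well-behaved data (a test checks they agree within ~15 %).

### Simulated assay design

EC50 recovery experiments simulate a 6-concentration assay with 50
animals per concentration, true EC50 1.5 mg/L and slope 3. The
concentration grid uses ~1.4x geometric steps bracketing the expected
EC50 (0.6–3.4 mg/L) — the design a range-finding pre-test yields, and
the efficient one: Fisher information gives SE(log EC50) ≈ 5 % there,
versus ~7 % for a wide 2x serial dilution, so a 10 % recovery tolerance
is a ~2-sigma statement. Recovery is assessed on the median of five
replicate simulated assays, which makes the check robust to individual
binomial draws while still reflecting single-assay precision.

## Synthetic scenes

The generator emulates one flow-cell view: dark ellipses (semi-axes
3–6 px, elongation 1.6–2.5, body intensity 60 shading toward the rim)
on a bright field (200) at 512x288 — a quarter-scale of a 2048x1088
camera — with Gaussian sensor noise (sigma 2), static droplets stuck to
the glass (mid-contrast circles, absorbed into the background mean),
and slowly drifting sediment clumps (0.05–0.2 px/frame) that leave
ghost smears in the difference image. Animal motion is a persistent
random walk, v <- 0.85 v + N(0, 0.5^2) per axis with reflective walls
(rms speed ~1 px/frame), deliberately *not* the tracker's
constant-velocity model so tracking tests are not self-fulfilling.
Animals exert a weak short-range repulsion on one another (within 3x
the largest semi-axis): real daphnia avoid contact, and the
segmentation stage does not attempt to split merged silhouettes, which
is out of scope. Ground truth records each animal's tight silhouette
box and mass centre per frame; nuisance objects are excluded.

What passing these tests shows: the chain is internally consistent and
recovers known motion under the stated imaging model. What it does not
show: robustness to occlusion and touching animals, illumination drift,
focus variation, or the texture statistics of real organisms — real
deployments should validate the classifier on annotated patches from
their own cameras (the patch-database format and `daphtrack train
--manifest` exist for exactly that).

## Problem sizes

Default test and reproduction runs use one 450-frame 512x288 scene
(5 animals, 5 nuisance objects), 200 patches per class for classifier
training, and 5 simulated assays of 300 animals for EC50 — sizes at
which every experiment completes in seconds on a single core while the
tracking problem (post-warm-up, 150 evaluated frames x 5 identities)
still exercises association, coasting and re-acquisition.
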