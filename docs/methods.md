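# Methods

`mousetrack` tracks two unmarked mice in a static, top-view arena and
classifies their social and non-social behavior. The system learns what the
animals look like *while it runs*: no pre-trained detector and no per-video
training set, only a single user-annotated reference contour. This note
describes the model, the parameters that matter, the numerical choices, and
what the synthetic-data experiments do and do not demonstrate.

## Pipeline overview

Frames pass through three stages.

1. **Preprocessing.** Each grayscale frame is rescaled so its global mean
   matches a target intensity (removing slow illumination flicker), a static
   background is estimated as the pixel-wise temporal median, and foreground
   pixels are those whose absolute background difference exceeds a threshold
   (between-class-variance maximization by default, a fixed value as manual
   fallback). 8-connected components above a minimum area `b_min` become
   blobs. Tails are removed by morphological opening with a disc of radius
   `r_S`; the tail base — used later to orient shapes — is the centroid of
   the intersection between the dilated tail component and the body.

2. **Separated regime: shape learning.** While the two animals form two
   distinct blobs, each body contour (resampled to `n = 100` equidistant
   points) is matched to the reference shape with inner-distance shape
   contexts: each point is described by a log-polar histogram (5 radial × 12
   angular bins) of the other points, where Euclidean distance is replaced
   by the *inner distance* (shortest path inside the silhouette) and the
   angle by the *inner angle* (first path direction relative to the local
   boundary tangent). Histograms are compared with the chi-square statistic
   and the optimal point correspondence is the minimum-cost assignment;
   its total cost `H` measures match quality. The correspondence transfers
   the reference landmarks (nose, tail base, both ears) to the new contour;
   the viewing direction is the ray from the ear midpoint through the nose.
   Matches with `H` below a gate `rho_max` enter the shape catalog after
   being rotated so the tail-to-nose axis is vertical (nose down) and
   centered on the axis midpoint.

3. **Crossing regime: model-based separation.** When the blobs merge, an
   active shape model trained from the catalog takes over. The model is a
   PCA of the aligned catalog shapes (mean, eigenvectors, eigenvalues, with
   the mode count chosen as the smallest prefix reaching a fraction `f_v`
   of total variance) plus per-landmark statistics of normalized
   first-derivative intensity profiles along the contour normal. Each
   crossing frame, both instances are initialized from the previous frame
   and refined by `N_max` alternating iterations; in every iteration the
   landmarks inside the current contour-overlap region (plus a 2 px margin)
   are frozen so the two models cannot collapse onto each other, each free
   landmark moves to the offset minimizing the Mahalanobis distance of its
   profile, a pose is re-estimated, and the shape coefficients are clamped
   to `|b_i| <= m * sqrt(lambda_i)`. Identity is carried by the per-animal
   model instance during contact and by maximum contour overlap between
   consecutive frames otherwise.

Behavior is read from the resulting trajectories: nose-nose contact (C1),
anogenital sniffing (C2), side-by-side contact (C3), following (C4) and
mating posture (C5) are geometric predicates on landmark distances, viewing
angles and silhouette overlap; self-grooming (C6) is detected from the shape
coefficients with a class-weighted RBF support-vector machine, validated
interval-wise (each time interval predicted by a model trained on the rest).

## Key parameters

| Parameter | Default | Meaning and rationale |
|---|---|---|
| `preprocess.b_min` | 200 px² | minimum blob area; well below a single animal (~2000 px² at the default scale), well above speckle |
| `preprocess.r_S` | 4 px | tail-removal disc radius; exceeds half the tail width (~3 px), stays below half the body width (~15 px) |
| `match.n_points` | 100 | contour samples; balances descriptor fidelity against the O(n³) assignment cost |
| `match.n_r`, `match.n_theta` | 5, 12 | log-polar bins, the customary shape-context configuration; radial edges log-spaced on [0.125, 2] of the mean inner distance |
| `catalog.c_v` | 0.5 | target acceptance ratio; the cost gate `rho_max` is calibrated from a warm-up cost sample so this fraction falls strictly below it. A fixed `rho_max` can be given instead — the two are mutually exclusive |
| `asm.f_v`, `asm.m` | 0.98, 3 | retained-variance fraction and coefficient clamp, the standard shape-model settings |
| `asm.N_max` | 60 | fit iterations per animal per frame; ample for frame-to-frame motion up to ~5 px at 25 fps |
| `asm.profile_k`, `asm.search_l` | 5, 7 | profile half-length and search half-range in px (1-px sampling, bilinear interpolation) |
| `tracker.min_catalog` | 50 | catalog entries required before the model may train; an earlier crossing raises an explicit error rather than guessing |
| behavior thresholds | see `BehaviorSection` | in body-length units (body length = median nose-tail distance over separated frames): C1/C2 0.25, C3 centers < 0.6 with headings within 30° of parallel or anti-parallel, C4 nose-behind-tail < 0.5 with heading difference < 45° sustained 0.5 s, C5 overlap > 40% with heading difference < 45° |

## Numerical and design choices

- **Visibility graph.** Inner distances are shortest paths over the
  visibility graph of the contour polygon. Chord visibility is decided by
  pure sign tests (interior angular sector at both endpoints, no proper
  edge crossing), not by sampling interior points: sign tests are stable
  under rigid motion of the vertex set, which makes the descriptors — and
  hence the matching cost of a rigidly moved copy — exactly invariant.
  Angles that fall exactly on a histogram bin edge (paths straight along
  the boundary) are snapped to the edge before binning for the same reason.
- **Correspondence regularization.** The optimal assignment is solved
  exactly (no dummy points; both contours have the same `n`). On nearly
  fore-aft-symmetric postures the raw assignment can mix the two symmetric
  solutions, so the correspondence is snapped to its dominant cyclic shift
  (disagreeing entries re-interpolated), smoothed with a circular median
  over ±3 neighbours, and each nose-to-tail side is re-spaced by arc
  length. The last step matters for the shape model: without it,
  correspondence jitter becomes spurious tangential variance modes that
  let a fitted contour slide along the silhouette.
- **Head/tail disambiguation.** The transferred landmarks are checked
  against the morphologically localized tail base; if the match put the
  nose there, the contour is re-matched in reversed traversal order. With
  no tail base (occlusion), the orientation closer to the previous frame
  wins. The first frame must therefore have a localizable tail.
- **Pose in the fit.** Catalog shapes are normalized by rotating the
  tail-to-nose axis onto the vertical, so the fit recovers the rotation in
  closed form from the same two anchor landmarks and the translation from
  all landmarks jointly. A similarity fit by least squares is deliberately
  not used for the rotation: bending modes look like rotations to least
  squares, and the alternation converges too slowly to be usable.
- **Profile search stabilizers.** Candidate windows with little edge
  energy are ineligible and landmarks that see no edge stay put (otherwise
  flat-interior profiles, which normalize to near-zero vectors, can have a
  deceptively small Mahalanobis distance and the contour drifts off the
  animal); suggested offsets are median-filtered along the contour;
  per-iteration movement is capped at 1.5 px; the discrete search settles
  into a small limit cycle, so `fit` averages the realized contours of the
  last 10 iterates. Profile covariances are shrunk toward the scaled
  identity (weight 0.2) before inversion — raw sample covariances are
  rank-deficient and reject even perfect edges.
- **Gate calibration.** `rho_max` depends on `n` and the bin layout and is
  scene-specific, so by default it is calibrated as the quantile of observed
  match costs with a fraction `c_v` strictly below: first from a 60-cost
  warm-up sample (candidate shapes collected during the warm-up are gated
  retroactively), then refit from the full cost history every 100 new costs
  — the warm-up alone is early-biased and lets the realized acceptance
  ratio drift away from the target on longer sessions.
- **Aggregate tracking error.** The summary error is the *mean* over
  evaluated frames of the per-frame average of nose and tail distances.
  A literal summed variant (no 1/N) is available via
  `evaluation.literal_sum` for comparability, but the mean is the default
  because only it yields scale-free, subpixel-comparable values.
- **Regime thresholds.** A blob counts as an animal above 0.4× the running
  median separated-blob area; a single blob counts as a merged pair above
  1.2× the median. Frames with neither pattern are flagged `lost` and the
  previous state is carried, never interpolated.
- **Model refresh.** The catalog keeps growing after the first model is
  trained (reservoir-thinned above 3000 entries); the model is retrained at
  the next crossing after every 500 separated frames.

## The synthetic-data generator

All quantitative claims in the test suite and the acceptance script are
made on synthetic sessions: two articulated mouse silhouettes (circular-arc
spine with a bend parameter, squash/stretch factor, elliptical head, two
ear bumps placed symmetrically about the nose tangent so the true viewing
direction is exactly the pose heading, and a 3-px tapering tail) rendered
dark on a bright background with multiplicative illumination drift (±2%,
period 200 frames) and Gaussian sensor noise (σ = 3 grey levels), at
480×480 px, body length 80 px, 25 fps. Rasterization is 4× supersampled,
emulating the partial-pixel coverage of real camera optics. Scripted
sessions provide per-frame ground truth (landmarks, viewing direction,
identity, silhouette overlap) and labeled behavior episodes: separated
wandering, k scripted crossings with moderate (≈30–50%) overlap, head-on
contact, anogenital sniffing, side-by-side contact, following, mounting
posture, self-grooming (body compressed to ~0.7 of its length), and a
low-contrast variant (animal grey 120 instead of 40).

What the generator does *not* emulate: fur texture and shading, shadows,
reflections on arena walls, motion blur, limb/whisker detail, cage bedding,
and genuinely erratic animal kinematics. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under controlled articulation, contact, noise and drift — not performance
on any particular real recording, where contrast, reflections and posture
variety are harsher.

## Problem sizes used in tests and the acceptance script

End-to-end tracking runs use a 300-frame session with three contact events
(and a 200-frame single-crossing session for the acceptance-ratio sweep
over c_v ∈ {0.15, 0.5, 0.83}); behavior scripts use 240 frames per
condition and 400 frames for grooming; oracle checks use 20 random simple
polygons (n = 40) against a shapely/networkx Dijkstra oracle and 50 random
assignment instances (n ≤ 7) against brute-force enumeration; shape-model
recovery uses 200 shapes from a known 2-mode generator. These sizes give
stable statistics while keeping a full run in minutes on one CPU.

## Known limitations

- Exactly two animals; more would need a different regime classifier and
  assignment logic.
- Identity through long, high-overlap contact (e.g. sustained mounting)
  rests entirely on the alternating fit; there is no appearance-based
  post-hoc identity correction.
- The first frames must show both animals separated, with localizable
  tails, long enough to fill the catalog (≥ `tracker.min_catalog` accepted
  shapes) before the first crossing.
- Behavior thresholds are heuristic defaults in body-length units; they are
  exposed in the configuration and should be reviewed against a labeled
  sample for any new arena or strain.
- The SVM grooming detector needs labeled grooming frames from the same
  session (or a compatible one) and both classes present in every training
  split of the interval-wise cross-validation.
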