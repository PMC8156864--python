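# Methods

This note documents the models and procedures implemented in `schooltrack`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test bed does and does not show
about real footage.

## Shape-index features

The grayscale frame is treated as a height field. At scale σ the Hessian
H = [[Lxx, Lxy], [Lxy, Lyy]] is computed by separable convolution with
sampled Gaussian-derivative kernels (reflect boundary, truncation at 4σ).
The kernels are *moment-corrected*: truncation leaves a sampled
second-derivative kernel with a small non-zero sum, so constants would not
map exactly to zero and the curvature of x² would read 1.91 rather than 2
at σ = 2. We restore the defining discrete moment conditions (zero mean and
exact response 2 to x² for the second derivative; exact response 1 to a
ramp for the first), which makes the polynomial test images in the suite
exact to machine precision and removes a small contrast-dependent bias from
all downstream fields.

The eigenvalues K₁ ≥ K₂ give the shape index
s = (2/π)·arctan((K₁+K₂)/(K₂−K₁)) ∈ [−1, 1], banded into the nine
Koenderink categories with left-closed intervals of width 1/4 (cup at
[−1,−7/8), …, cap at [7/8, 1]). Conventions: a *dark* local minimum scores
−1 (cup) and a dark line −1/2 (rut); umbilic points K₁ = K₂ ≠ 0 take the
directional limit ∓1, and fully flat points are explicitly *undefined* and
excluded from every category mask (otherwise blank background would
classify as something). Note that `skimage.feature.shape_index` shares this
convention but divides by K₁−K₂ without guarding the umbilic limit, so it
is unstable exactly at perfect extrema; the test suite compares against it
only away from |s| ≈ 1.

No γ-normalization of scale-space responses is applied: the index is a
ratio of eigenvalues and the category thresholds are scale-free.

### Scales

σ_ridge = 4 px and σ_head = 8 px by default, matching the scales at which
the body centerline reads as a rut and the head as a cup for fish of the
size the defaults target (≈60 px long, ≈12 px wide, head ≈14 px across). A
usable rule of thumb: σ_head ≈ half the head width, σ_ridge ≈ a third of
the body width. Both are configuration fields, as is the centerline
polarity (`dark` fish on bright background, the default; `bright` swaps rut
for ridge and cup for dome/cap for inverted footage).

## Segmentation

Background = per-pixel temporal median of the first `n_background` (50)
frames; even counts take the lower central value so integer inputs give an
exactly representable background. Foreground = |background − frame| >
`diff_threshold` (25, ≈10% of the 8-bit range; absolute difference so both
polarities work), 8-connected components, area-filtered to
[`area_min`, `area_max`] = [100, 50 000] px². Coordinates are 0-based,
origin top-left, x rightward along columns; boxes half-open. Blobs carry a
*context patch* — the tight box inflated by 4·max(σ) px — so scale-space
filters see real image content beyond the box. Where the context would
leave the frame it is filled with background content rather than a mirror
image: outside the imaged arena there is no fish, and reflect-padding a
fish touching the frame edge would destroy its head's cup signature. The
background is static for the whole video; no rolling update.

## Head detection

Cup-category mask at σ_head restricted to blob pixels, morphologically
closed with a disk of radius σ_head/4 (a strongly bent fish can pinch its
concave head region into two fragments; closing merges fragments of one
head without bridging distinct heads, which sit several σ apart), then
8-connected components filtered to [`head_area_min`, `head_area_max`] =
[18, 400] px². The lower bound separates genuine heads (≈60 px² at the
default geometry, ≈20–40 when strongly bent) from the small spurious cups a
body's tail cap can produce (≤13 px²). Each surviving component's tight
bounding box, translated to frame coordinates, is one head detection.

## Body detection

1. **Centerline mask.** Rut-category pixels at σ_ridge within the blob,
   with two cleanups. First, every blob-scale dark region (head disk, tail
   cap) is wrapped by a ring of rut-category pixels at its inflection
   radius; chords through such a ring masquerade as body lines at arbitrary
   angles. Rings encircle a concave (cup/trough) component at the same
   scale, so rut pixels within 1.5σ of any concave component of area
   ≥ 2σ² are removed (speckle-sized concave pixels cast no halo — they are
   curvature noise along the band edge, and dilating them would shred the
   centerline). Second, the surviving band — which can be as wide as the
   fish body, since the category depends only on the eigenvalue ratio — is
   thinned to the valley floor by non-maximum suppression of K₁ along its
   own eigenvector (the across-line direction), with bilinear sampling at
   ±1 px. Unlike a medial axis, this thinning does not fork at blunt band
   ends.
2. **Hough lines.** Standard (ρ, θ) transform of the thinned mask, θ
   resolution 1°, ρ resolution 1 px. Peaks are plateau-inclusive local
   maxima *along ρ within each θ column* with at least
   max(5, 0.25·max votes) votes. Per-column peaks (rather than one global
   maximum) deliberately return a redundant bundle of lines per fish — a
   digital straight line spreads votes over neighbouring θ bins, and the
   clustering stage needs several samples per fish. Each peak is then
   refined by two iterations of PCA over its inlier pixels (within 1.5 px
   of the line): collinear chords of one straight centerline collapse onto
   the same sub-bin-precision line, while chords of a bent centerline
   settle on their local tangent. The refinement is what makes the motion
   state sharp: a straight fish's ω reads 0 rather than the ±5–20° smear
   raw accumulator quantization produces.
3. **Clustering.** DBSCAN over (ρ/10 px, θ/10°) with eps = 1.0,
   min_samples = 3; the pairwise metric takes the minimum over the two
   representations (ρ, θ) and (−ρ, θ±π) of each line, so bundles straddling
   the 0/π seam stay together. Noise lines are dropped; each cluster is one
   fish candidate.
4. **Summary.** R = argmin Σ(x cosθⱼ + y sinθⱼ − ρⱼ)². When the normal
   equations are near-singular (parallel bundle, eigenvalue ratio < 1e−4)
   the intersection is unconstrained along the line, so R falls back to the
   mean of the lines' inlier centroids — a point on the fish — or, for
   lines constructed without pixel support, to the centroid of the
   per-line foot points of the origin. ω = max θ − min θ in degrees after
   unwrapping θ across the seam about the circular mean (period π), capped
   at 180°. The cluster's circular-mean direction + π/2 is carried as the
   *body axis*, used by the tracker's fallback path. Heads and bodies are
   not paired at detection time; association to identities is entirely the
   tracker's job, so either feature can recover a fish the other missed.

## Parallel tracking

Per feature kind (head primary, body secondary), the same machinery runs
each frame:

1. Confirmed tracks Kalman-predict; the predicted box is centered on the
   predicted position with base size (24×24 px heads, 40×40 px bodies)
   inflated by 1 + k·ω/180 (k = 1): the motion state widens the association
   gate exactly for the fish whose motion the constant-velocity model
   predicts worst. The Kalman state is (u, v, u̇, v̇) only — a top-view
   fish head has essentially constant apparent size, so the usual
   scale/aspect states are dropped; the filter uses a white-acceleration
   process noise (scale 1 px/frame²) and 1 px² measurement noise, with a
   large initial velocity variance so the second observation effectively
   sets the velocity.
2. Hungarian assignment on cost 1 − IOU, then the SORT gate: matches with
   IOU < `iou_min` (0.1) are cancelled after optimization.
3. Leftover detections run the same assignment against the temporary-track
   pool; still-unassigned detections spawn new temporary tracks. Temporary
   tracks unassociated for more than `max_age` (5) frames are discarded as
   noise; those reaching `min_hits` (3) are promoted. Promotion takes the
   lost ID whose last-known position — *extrapolated by its last velocity*
   to the current frame — is nearest, else a fresh ID. Two safeguards
   handle re-appearance after detection gaps: a ripe temporary within 1.5
   head-box diagonals of a confirmed track that failed to match its own
   feature this frame is *adopted* (the starving track snaps onto the fresh
   measurement instead of a duplicate identity being minted), and while any
   confirmed track is starving with an empty lost pool, promotions wait, so
   a dying track's ID is recycled rather than shadowed by a new one.
4. Confirmed tracks unmatched for more than `max_age` frames retire their
   ID to the lost pool (IDs are reused at most once).

The two trackers cooperate through pairing and fallback. A body track
becomes paired to the head identity whose track center lies inside the body
box while both are matched, recording the head-minus-body offset and the
body axis at that moment. When a head track goes unmatched but its paired
body track is matched, the head is updated to body center + offset, with
the offset rotated by the change in body axis (resolved modulo π to the
smaller rotation) — a fish that turns while its head is hidden still gets a
valid estimate. A plausibility gate (estimate within 1.5 head-box diagonals
of the track's own prediction) stops a stale pairing from dragging a track
onto the wrong fish; failing that the track coasts on its prediction, and
after `max_age` frames its identity enters the lost pool for relinking.
Records are emitted only for confirmed head tracks (the `min_hits` burn-in
is silent) and carry a provenance flag: `head_tracked`, `body_fallback`, or
`coasted`.

Tracking is online by construction — the state machine consumes one frame
at a time and the streaming and batch entry points are the same code; a
test asserts their outputs are identical. The only whole-video input is the
background image, built once from the first `n_background` frames.

## Evaluation

Per frame, predicted head points are matched to truth head points by
Hungarian assignment on Euclidean distance with gate `dist_max` (30 px,
half the default fish length). Matched pairs are TP, unmatched predictions
FP, unmatched truth FN. A truth fish's *established* ID is the first
predicted ID matched to it; a frame counts toward CTR only when the matched
ID equals the established one. ID switches are counted the standard MOT
way (changes of a truth fish's matched ID between its matched frames).
Occlusion events are maximal runs of frames with any truth occlusion flag;
an event's identity outcome is judged at the first post-event frame where
all involved fish are matched (all must carry their established ID), and an
event is "detected" if every involved fish was matched in at least half of
its frames. Events whose run touches the final frame have no post-event
frame and are excluded from the CIR denominator as unjudgeable rather than
scored as failures. Ratios are reported as percentages, rounded to 2
decimals in reports while raw fractions are kept internally.

## The synthetic school

The simulator generates what the detector is built for: dark bendable fish
with darker heads on a bright backlit arena.

* **Appearance.** Each fish is a 5-segment polyline stroked as a capsule of
  width 12 px and length 60 px at intensity 160, with a head disk of radius
  0.58·width at intensity 30, on background 230; overlapping fish compose
  by the minimum rule (darker silhouette wins), and Gaussian pixel noise
  (sd 2) is added after rendering and clipped to [0, 255]. The level
  ordering head < body < background encodes the physics of backlit imaging:
  the head (eyes, skull) is opaque while the juvenile body is
  semi-transparent. The body level matters for the detector's head model —
  were the body nearly as dark as the head, the along-body curvature at the
  head would be too weak for the cup band (the cup requires K₂/K₁ > 2/3).
* **Kinematics.** Heading follows an AR(1) random walk (persistence 0.85,
  innovation sd 0.03 rad, rate clipped to ±0.15 rad/frame) at constant
  cruise speed 2.5 px/frame; body bend tracks the turn rate (target
  5×rate, clipped to ±0.6 rad, relaxation 0.4/frame), so turning fish bend
  and straighten like real ones. Walls steer the heading toward the
  specular reflection target at a capped turn rate (0.35 rad/frame) — an
  instantaneous reflection would rotate the whole body in one frame and
  teleport the head by up to ~50 px, which neither real fish nor any
  constant-velocity tracker exhibits/handles. Fish avoid each other within
  90 px by steering away from the nearest neighbour (strength growing as
  the gap closes), which keeps "no crossing" test suites honest; scripted
  crossing pairs ignore avoidance.
* **Scripted crossings.** A crossing script ((t₀, t₁), (a, b)) runs a
  leader–striker choreography: fish *a* cruises its own path while fish *b*
  first moves to a point abeam of the leader (on an intercept course at
  1.5× cruise), then cuts across the leader's mid-body at 1.3× cruise;
  once silhouettes are within contact range both lock headings and swim
  straight through, and the script releases them at t₁. Walls override the
  choreography in every phase. This produces oblique, transversal crossings
  of a few seconds — the scripted range must be long enough for the initial
  separation (roughly separation/speed frames). Degenerate long antiparallel
  grazes, where two heads merge for dozens of frames, are deliberately not
  generated: no appearance feature at a fixed scale can separate them, and
  severely occluded fish are not detection targets for this method.
* **Ground truth.** Per frame and fish: head point (front chain vertex),
  body center (arc midpoint), bend, and an occlusion flag set exactly when
  the rendered silhouette shares ≥1 pixel with another fish's. One RNG
  seeded from `seed` drives placement, kinematics and noise, so output is
  bit-identical across runs.

**What the synthetic suites do and do not show.** They exercise the full
algorithmic chain — scale-space feature extraction, redundant-feature
recovery, lifecycle logic, identity maintenance through genuine pixel-level
occlusions — under exactly known truth, which is what the unit and
acceptance suites need. They do not emulate uneven illumination, water
surface ripple, tank-wall reflections (a major FP source in real rigs),
body texture, motion blur, or 3-D attitude changes that shorten the
apparent body. Perfect scores on the simulator therefore bound the
algorithm's logic, not its performance on any particular recording; on real
footage the detection thresholds and scales must be set to the fish size
and contrast at hand.

## Problem sizes and numerical choices

The acceptance script and test suite run at desk scale, chosen to exercise
every code path while keeping a full run in minutes on one CPU: a
5-fish/200-frame clean school (CTR, precision, recall, ID switches, scored
after a 10-frame burn-in), twenty 2-fish/110-frame scripted-crossing runs
in a 320×320 arena (CIR and detection rate from occlusions), 20 random
single-fish frames plus 8 straight/bent ω pairs for the detector, and 200
random cost matrices (≤6×6) against exhaustive enumeration for the
assignment stage. Closed-form shape-index identities hold to 1e−12;
trace/determinant conservation and image-negation antisymmetry hold to
1e−9 on random 64×64 images. Tolerances on detector geometry are 5 px
(body point to true centerline) and containment (truth head inside the
head box); the straight-fish motion state is required to vanish within one
accumulator θ bin (1°) in the median over headings. Tie-breaks: assignment
uses scipy's deterministic Hungarian implementation with matches reported
in row order; DBSCAN clusters are returned in order of their first member;
all simulator randomness flows from a single `numpy` generator.

## Known limitations

* Identity maintenance degrades for long, near-parallel grazes where both
  heads merge at σ_head for many frames; the redundant body feature cannot
  help once the centerline clusters merge (antiparallel fish have the same
  θ modulo π). The practical remedy — higher frame rates, which keep
  per-frame motion near-linear — is reflected in the suite's frame-rate
  degradation property rather than solved algorithmically.
* The background is static; slow illumination drift or a moved arena
  invalidates it.
* Appearance is not used for re-identification: after a total track loss
  longer than `max_age` with no body support, relinking is purely motion
  based and can swap visually identical fish.
* Video-file output is not provided in this environment (no lossless codec
  backend); frame sequences are written as numbered PNGs, and video input
  is supported only through whatever imageio can decode.
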