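# Methods

## The problem

Starling flocks raid ripening fruit; scaring devices that fire on a
schedule lose their effect as birds habituate.  The system modeled here
fires the actuator only when a *flock* — five or more birds flying
together — is optically detected with sufficient confidence.  The
package implements the software chain of such a system (motion
detection, classification with flock grouping, evaluation, trigger
policy, coverage planning) together with a synthetic scene generator
that stands in for field footage.

## Motion detection

For consecutive grayscale frames `I_t`, `I_{t-1}` the detector
computes, per frame:

1. `D_t = |I_t − I_{t-1}|` — absolute difference.  The sign of an
   intensity change carries no information for motion presence, so the
   magnitude is used; the operation is commutative.
2. `A_t = (1 − α)·A_{t-1} + α·D_t` — the accumulated differential
   background, an exponential moving average with rate `α`
   (default 0.05), started at zero.  Of the possible accumulation
   schemes (unbounded sum, sliding window, EMA), the EMA was chosen
   because it decays stale motion and has a single interpretable
   parameter.  Against a stationary flicker source of constant
   difference `D`, the accumulator converges geometrically:
   `A_k = D·(1 − (1−α)^k)`.
3. `F_t = max(D_t − A_t, 0)` — background subtraction, clamped at zero
   (negative evidence is meaningless for a binary detector).
4. `M_t = F_t > θ` — binarisation at threshold `θ` (default 25 of 255).
5. Connected components of `M_t` with at least `min_area` pixels
   (default 4) become tight bounding boxes, 8-connected so that small
   distant birds with 1-px diagonal gaps still form one object.

Quivering leaves flicker the same pixels every frame, so their
difference signal accumulates into `A` and is subtracted away: a patch
of swing ±18 (consecutive difference 36) falls below the default
threshold within 7 frames of warm-up; the package's stated guarantee is
silence after 10 frames for any flicker whose difference stays below
`θ + A`.  A bird keeps hitting fresh pixels, so its signal never
accumulates locally and survives the filter.

Conventions fixed once and enforced by tests: boxes are 0-based and
half-open (`[x0, x1) × [y0, y1)`); box lists are sorted by `(y0, x0)`;
frame 0 initialises the state and emits no detections; color input is
converted to 8-bit grayscale (ITU-R 601 luma) before differencing.  The
vectorised pipeline is verified pixel-exactly against a pure-Python
double-loop reference (`flockwatch._naive`) on random sequences; the
reference reproduces the uint8 truncation of the fast path.

## Classification and flock grouping

The deployed system's CNN is out of scope here; the package defines the
classifier *contract* (frame + candidate boxes → labeled detections
with confidence) and ships a heuristic reference implementation used to
exercise the rest of the pipeline: blobs of ≤ 2 px area are bugs,
≥ 225 px helicopters, everything between a bird, with confidence an
increasing function of area.  These rules are a stand-in with no
claim about field accuracy.

"Five or more birds flying together" is operationalised as
single-linkage clustering of bird-box centers at a proximity threshold;
the default proximity is 4× the median bird-box diagonal, since birds
of one flock are imaged at a similar distance and their apparent size
sets the natural spatial scale.  Clusters of ≥ 5 birds are replaced by
one flock detection whose box is the cluster hull and whose confidence
is the mean member confidence (the natural unweighted choice; no
member dominates).  Clusters of ≤ 4 pass through unchanged, so no
object is ever lost and the output is invariant under input
permutation.  Classifiers may equally emit flock boxes directly — both
paths coexist.

## Evaluation

Detections are matched one-to-one to annotations when IoU ≥ 0.5.  Since
only the overlap prerequisite is standard, the assignment procedure had
to be fixed: greedy in descending detection confidence, each detection
claiming the highest-IoU free annotation, ties broken by lower
annotation index.  Greedy-by-confidence is the convention of the common
detection benchmarks and is stable under list permutation when
confidences are distinct.  Labels are ignored at match time; a
cross-class match counts as FP for the predicted class **and** FN for
the true class, which is exactly what reconciles per-class FP/FN
columns with a confusion matrix whose off-diagonal cells are rare.
Unmatched detections are tallied per predicted class as *out-of-class*
false positives (objects overlapping no annotation at all).

The error rate uses TN = 0: object detection has no natural
true-negative count, and this convention reproduces the field trial's
printed error rates exactly.  All percentages are rounded half-up to
one decimal, matching how such tables are printed.

`flockwatch.fieldstudy` ships the field-trial benchmark tallies
(898/71/35/4 ground-truth objects per class, 1008 total, with their
confusion cells).  Running the evaluator on a fixture realizing those
tallies reproduces every *reconcilable* report cell: all four recalls
(83.4, 67.6, 94.3, 100.0), all four error rates (28.2, 49.5, 5.7, 0.0),
and flock/helicopter precision (100.0) and F1 (97.1, 100.0).  The
trial's printed bird precision/F1 (83.4/83.4) and bug precision/F1
(65.8/66.7) do **not** follow from the tallies under the standard
formulas (which give 83.8/83.6 and 66.7/67.1); they came from the
external training service's own reporting and are deliberately not
reverse-engineered.  The package computes and reports the formula
values.

## Trigger policy

An event is emitted when a flock-labeled detection with confidence
≥ 30 % (inclusive — "at least") has been present for `confirm_frames`
consecutive frames and no event fired within `cooldown_frames`.
Defaults (`confirm_frames=1`, `cooldown_frames=0`) reproduce the basic
fire-on-sight behaviour; confirmation models the observation that a
real flock persists across frames, and cooldown is an addition to model
actuator duty limits.  Individual birds never trigger.  Lowering the
threshold can only add events (monotonicity), and consecutive events
are at least `cooldown_frames + 1` frames apart; both are property
tests.

## Coverage planning

A camera with horizontal field of view `f` degrees and 300 m range
covers a circular sector; full-panorama coverage needs `360/f` cameras,
reported to one decimal (half-up) with a nearest-integer
recommendation: 44.6° → 8.1 (8), 64.5° → 5.6 (6), 21.8° → 16.5 (17).
Sector membership is inclusive at both the angular edge (offset exactly
FOV/2) and the range boundary (exactly 300 m), with a 1e-9 float
tolerance at the angular edge.  A ring of `n` evenly spaced cameras
with FOV ≥ 360/n covers every bearing, checked exhaustively at 1°
steps.

## Synthetic scenes

The generator emulates what the field cameras record, not how it
looks: a flat background (default level 120) with additive Gaussian
sensor noise (σ = 2 intensity levels — real sensors are not noiseless,
and a nonzero floor keeps the default threshold honest), square
intensity blobs for objects, and flickering rectangular quiver patches.
Class size scales follow the qualitative size/distance relations of the
field imagery: birds a few px (default 3), bugs 1–2 px with large
random-walk steps (near the lens, hence fast and erratic), helicopters
≥ 15 px and slow.  Flock members sit on a staggered two-row formation
with configurable pitch, share the flock velocity, and jitter by ~0.4 px
per frame; the per-frame flock annotation is the hull of the member
boxes.  All randomness flows from one `numpy` Generator seeded by the
config, so identical configs give byte-identical output.

What the simulator does *not* reproduce: photorealistic texture,
illumination changes, wind-driven global motion, perspective, or the
true appearance statistics of starlings — so passing tests demonstrate
the correctness and self-consistency of the software chain, not field
accuracy of any classifier.

The benign reference scene (240×160 px, 20 frames, three
well-separated high-contrast flocks of six birds moving at 2–3
px/frame) is the standard end-to-end benchmark: simulator → detector →
heuristic classifier → evaluator must achieve ≥ 90 % flock recall.
Recall is scored from frame 1 because frame 0, by contract, only
initialises the detector; measured values are 93–100 % depending on
seed.  `make_fixture_from_counts` serves the complementary abstract
path: it lays disjoint unit boxes on a grid so that matching reproduces
any internally consistent set of tallies exactly, and rejects
inconsistent requests.

## Problem sizes and numerical choices

The oracle-equivalence check uses 100 random 16×16 five-frame
sequences; quiver suppression uses a 64×48, 40-frame scene; the
end-to-end benchmark the 20-frame reference scene — sizes at which the
pure-Python reference and exhaustive checks stay near-instant while
still exercising every code path.  Percentages use exact decimal
arithmetic before half-up rounding; box geometry is integer throughout,
so IoU values are exact rationals.

## Known limitations

- The heuristic classifier is a plumbing stand-in; real deployments
  should adapt a trained detector behind the `Classifier` contract.
- Greedy matching is not globally optimal (Hungarian) assignment; for
  the IoU patterns produced here the two coincide, but pathological
  overlap patterns can differ.
- The coverage planner treats sectors on flat terrain; altitude
  profiles and non-circular segment layouts are out of scope.
- Trigger debouncing of one persistent flock beyond the cooldown
  mechanism is not modeled.
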