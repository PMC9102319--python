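# Methods

## Problem and scope

Given a depth video — per-frame 2D arrays of sensor-to-surface distances,
with 0 marking invalid ("hole") pixels — produce per-frame binary masks of
one target object (typically a human body) from minimal user input. The
package implements the full pipeline: denoising, point-cloud indexing,
bounding-box clustering, mask-editing semantics, propagation across
frames, an accuracy metric, and a synthetic scene generator that stands in
for non-redistributable sensor recordings.

## Noise reduction

Depth maps are bilateral-filtered before clustering:

    I'(p) = Σ_q w(p,q) I(q) / Σ_q w(p,q)
    w(p,q) = exp(−|p−q|² / 2σ_d²) · exp(−(I(p)−I(q))² / 2σ_r²)

over a square window of half-width `radius` (default ⌈3σ_d⌉, ≥ 1, which
captures >99% of the spatial Gaussian mass). Defaults σ_d = σ_r = 0.8.
Numerical choices:

- **Holes.** Pixels with I(q) = 0 are excluded from numerator and
  denominator; a hole centre stays 0. Without this, holes drag their
  neighbourhood towards 0 and can detach an object from itself.
- **Borders.** The window is truncated at the image edge — no padding, so
  no invented depths.
- **σ_r units.** σ_r lives in the depth values' native units. With raw
  u16 millimetre data, σ_r = 0.8 makes the range kernel nearly a hard
  edge detector; callers working in other units should scale σ_r
  accordingly. The pipeline exposes it (and a `--no-filter` bypass)
  rather than guessing a normalization.

The filter is a convex combination of valid inputs, hence output values
stay within the valid input range, constants are fixed points, and for a
two-level step (10 vs 100 at σ_r = 0.8) each side keeps its level to
within 1e-6 — the quantitative sense of "smooths noise but preserves
edges".

## Point cloud and kd-tree

Valid pixels lift to points (px·s_x, py·s_y, depth·s_z); default scales
are 1, so the clustering margin *b* is expressed in pixel/depth-value
units. The points are indexed in a 3D binary search tree splitting on x,
y, z cyclically. Production trees use a balanced median build
(deterministic: stable sort, ties to input order); a sequential-insertion
build exists to construct deliberately degenerate trees for adversarial
fixtures.

Extraction uses **lazy removal**: a returned point is flagged `removed`,
and each node maintains `subtree_active` (any unassigned point below or at
the node), recomputed bottom-up during every traversal. Searches skip
subtrees with `subtree_active == False`; this is the only pruning in the
default box-search traversal (see "Node-visit accounting").

Per point this representation costs 48 payload bytes (three 8-byte
coordinates, two 4-byte pixel indices, an 8-byte reference) plus 22 bytes
of tree overhead (two child references, two flags, a 4-byte split axis):
70 bytes total. At 640×480×30 fps this is why long sequences are
processed in windows rather than loaded whole; `plan_chunks` produces the
window plan and windowed propagation is exactly equivalent to a
whole-sequence run (chaining is sequential either way).

## Clustering

A cluster seeded at P with margin b > 0 is the fixpoint of the box
closure: start with box = P ± b; any unassigned point inside the box
joins, and the box becomes the hull of the members enlarged by b per
dimension; repeat until stable. Three algorithms:

- **fixed** — one tree pass per closure step; terminates with one empty
  confirming pass.
- **expanding** — the box is enlarged around each point the moment it is
  collected, inside the running traversal. A pass may still miss points
  whose subtree was visited before the box reached them, so passes repeat
  to the same fixpoint — but compact objects typically need a handful of
  passes instead of one per growth step. Fixed and expanding provably
  produce identical clusters (the expanding box never exceeds the final
  closure box, and always covers the fixed box pass by pass).
- **euclidean** — classic region growing by per-point radius search
  (radius = b, the shared parameter). This baseline computes BFS over the
  ≤ b distance graph; since a b-ball fits in a ±b box, its cluster is
  always a subset of the box cluster for the same seed.

Full-image segmentation repeatedly seeds at the first unassigned point in
row-major pixel order (a deterministic choice; the partition produced by
the box algorithms is seed-order-invariant, cluster numbering is not).

### Node-visit accounting

Benchmarks count a node as visited when its containment or distance test
executes. The default box-search traversal descends into every child that
still contains an unassigned point (activity pruning only). Under this
cost model a pass costs the same for both box algorithms in the same
removal state, and since the expanding variant's collected set dominates
the fixed variant's pass by pass, **visits(expanding) ≤ visits(fixed) on
every input** — with equality exactly when no pass is saved, as on the
adversarial chain fixture.

An optional half-space accelerator (`halfspace=True`) additionally skips
children whose coordinate half-space cannot meet the current box. It
never changes results (tested), and the interactive session/evaluation
paths use it for speed; but it is excluded from benchmark accounting
because mid-pass box growth weakens it asymmetrically — on a two-point
cluster both algorithms need two passes while the expanding pass prunes
strictly worse after growing, which would break the economy guarantee by
a fraction of a percent on sparse clouds. Nearest-neighbour and radius
searches always use standard splitting-plane elimination.

### Worst-case fixture

A collinear chain with spacing 0.9·b, inserted in descending order into a
degenerate (chain-shaped) tree and seeded at the leaf end, makes every
closure step add exactly one point while the traversal visits points in
an order the expanding box cannot exploit: both box algorithms need n−1
productive passes and identical visit counts. The generator is
self-validating — it runs both algorithms and asserts the property before
returning (trying a bounded set of insertion orders, and failing loudly
for disconnected spacings). Note that seeding the same tree at the chain
*root* instead yields the expanding algorithm's best case (one pass), so
the fixture pins the seed-selection order explicitly.

## Mask sessions

A frame's mask is rendered from an ordered action stack:

- `manual` / `erase` carry a set of brush pixels (square selector of
  half-width `brush`). Their mask contribution is the raw pixel set
  (user intent is 2D and depth-independent); their *realized points* —
  the subset with valid depth — are flagged removed in the tree **before
  any auto action runs**. This is the artificial-wall contract: a
  human-marked border blocks automatic growth across a bleeding edge.
- `auto` seeds an expanding-box cluster at the cloud point of the stored
  pixel (falling back to the 2D-nearest active point when that pixel is a
  hole or already assigned), with margin b.

Final mask = (manual pixels ∪ auto cluster pixels) − erase pixels; erased
pixels can never be 1. Replay is a pure function of (frame, stack); undo
pops the last action and re-renders.

### Propagation

Manual and erase actions transfer their exact pixel sets to the next
frame. An auto action's seed is recomputed: the next frame's cloud is
searched for the nearest neighbour (3D Euclidean, kd-tree) of the
previous frame's *realized* seed point. On a static scene this returns
the identical point (distance 0); on a moving object it follows the
surface, because the true object surface is a few pixels away while the
background behind the old seed is far away in depth. Two guard rules:

- a recomputed seed farther than `seed_jump_limit` (default 10·b) from
  the previous point is recorded as **failed** — a jump an order of
  magnitude beyond the clustering margin means the surface is gone, not
  moved — and contributes nothing to the mask;
- a failed seed stays failed in subsequent frames rather than re-latching
  onto whatever now occupies the original click pixel.

This is what makes an object leaving the scene produce failed-seed
records and empty auto masks instead of silently segmenting background.
Frames chain strictly (frame k derives from frame k−1), so batch size and
window size are pure throughput parameters with bitwise-identical output.

## Accuracy and the automatic benchmark

Accuracy between predicted mask A and ground truth G is precision ×
recall, |A∩G|²/(|A|·|G|): symmetric, 1 only for exact agreement, 0 for
disjoint masks. Both-empty scores 1 by convention and is logged as
degenerate. Sequence reports add mean, median and a fixed-width 0.04
histogram over [0, 1].

The automatic benchmark seeds at the ground-truth point nearest the
ground-truth centroid ("a click near the middle of the object",
deterministic with ties to row-major order), grows an expanding-box
cluster, and stops after any productive pass at which the cluster has
reached 90% of the ground-truth size — a cap against runaway growth
through bleeding edges. The cap is checked per pass, never mid-pass, so
the final pass may overshoot it (on an isolated object the sweep
typically ends > 99% complete; a cap checked per point would freeze every
run at exactly 90% recall, which no observed accuracy distribution is
consistent with). Margins b = 1…9 are swept and the best accuracy wins,
ties to the smaller b, because the right margin is scene-dependent.

## Synthetic scenes

The generator emulates a closed-room recording: a far wall at constant
depth (default 200 units), a floor occupying the bottom 30% of rows with
a linear gradient towards the camera (to 140 units), and a human-like
figure (head, torso, arms, legs from ellipse/rectangle primitives, slight
ellipsoid bulge) at ~100 units, i.e. ≥ 39 units in front of the nearest
background — unreachable for any margin b ≤ 9, so a clean figure is
exactly recoverable. Options: a thin figure-to-floor depth ramp (step 3
units/pixel) that creates a genuine bleeding edge; per-frame (dx, dy)
translation; an exit frame after which the figure is absent. Noise is
applied after ground-truth capture, in the order Gaussian → spikes →
holes → flicker (a per-frame offset applied only to valid pixels, so
holes survive), with a contract that the figure/background gap stays
≥ 5 Gaussian sigmas unless fusion is requested. Default noise magnitudes
(σ = 1.5 units, 2% holes, 0.5% spikes of magnitude 40, flicker σ = 0.5)
are plausible for consumer depth sensors in these units.

What a green test on synthetic scenes does **not** establish: performance
on real sensor data with correlated (surface-angle- and
distance-dependent) noise, motion blur, self-occlusion, or non-rigid
deformation — the generator's figure is rigid, its noise is i.i.d., and
its depth gaps are generous by construction. The synthetic results
validate the algorithms' contracts, not field accuracy.

## Known limitations

- Orthographic pixel-space coordinates (no camera intrinsics); metric use
  requires caller-provided (s_x, s_y, s_z) scales.
- No temporal filtering; flicker is generated but not removed.
- Pure-Python tree traversal: fine at 160×120-class resolutions, roughly
  two orders of magnitude from sensor-rate 640×480 throughput.
- The Euclidean baseline reproduces documented radius-growing semantics,
  not any specific library's implementation details.
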