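# Methods

## Data model

A fingerprint set is an ordered bit matrix: one row per trajectory frame,
one column per (ligand, residue, interaction type) key. Interaction types
come from a closed 16-name vocabulary (Anionic, CationPi, Cationic,
EdgeToFace, FaceToFace, HBAcceptor, HBDonor, Hydrophobic, Interaction,
MetalAcceptor, MetalDonor, PiCation, PiStacking, XBAcceptor, XBDonor,
VdWContact). The catch-all `Interaction` type is accepted by the loader
but carries no glyph; `VdWContact` is typically dropped before analysis
(`drop_interaction_types`) because, when enabled upstream, it subsumes
more specific interaction assignments.

Frames are 0-based and treated as uniformly spaced; the pipeline operates
on frame counts only and never needs physical time. Replicates of the same
system are concatenated and treated as a single entity by default (both
smoothing windows and run-length encoding may span replicate boundaries);
`per_replicate=True` restarts windows and runs at each boundary for users
who consider cross-boundary mixing inappropriate, since replicates are
independent simulations.

When replicates or two compared sets disagree in their detected
interactions, column spaces are unioned and absent columns zero-filled.
The union is ordered deterministically by (residue number, residue name,
interaction type, ligand). Determinism here is load-bearing: the
Rogers–Tanimoto denominator counts matched zeros, so the merged length —
and hence every similarity value — must not depend on input order.
Inputs already sharing one column list pass through unchanged, which makes
merging idempotent.

## Filtering

* **x₁** (window fraction, default 0.01): window width
  `w = max(1, round(x₁·n))` frames, round-half-to-even for platform
  determinism. At 75,000 frames, x₁ = 1% gives w = 750.
* **x₂** (occurrence threshold, default 0.20): a windowed mean is mapped
  to presence iff strictly greater than x₂. The strict inequality is
  deliberate — it makes x₂ = 0 a meaningful "any occurrence in the
  window" level, which is part of the default sweep grid.

The window is centred; for even `w` it spans `(w−1)//2` frames before and
`w//2` after the current frame. At the trajectory ends the window
*shrinks* to the frames that exist, so the fingerprint count always equals
the frame count. Shrinking (rather than zero-padding) keeps constant
columns exactly constant — an all-ones column smooths to 1.0 everywhere —
at the price of edge windows over-weighting nearby transients: a lone
spike inside the first `w/2` frames can exceed a threshold that the
full-width mean would clear. Users filtering data with important features
at the trajectory ends should be aware of this convention.

Intuitively the compound filter deletes interactions present for less than
about `x₂·w` consecutive frames. At the recommended 1%/20% on a 75k-frame
trajectory that is ~150 frames — the timescale of side-chain fluctuation
rather than of a maintained contact.

The `sweep` operation evaluates the default grids
(x₁: 0.5–10% in 8 steps; x₂: 0–40% in 12 steps) and records, per grid
point and aggregation mode, the surviving fingerprint and interaction
counts. Interaction counts are a property of the filtered matrix alone and
are identical across modes; fingerprint counts need not be monotone in x₂
(means sitting close to the threshold can split runs as it moves, giving
U-shaped curves). The tool reports the sweep; it deliberately does not
auto-select x₁/x₂, which remain a per-data-set judgement.

## Aggregation

*Interaction-based*: unique rows, id'd in first-occurrence order, with
total occurrence counts and member frame lists. *Time-based*: run-length
encoding — one entry per maximal run of identical consecutive frames.
Always `|interaction| ≤ |time| ≤ n_frames`, with equality gaps created by
revisited states. `find_identical_within` cross-links time-mode entries
with zero differing bits (revisited states); collapsing its equivalence
classes reproduces the interaction-mode set exactly, a property the tests
enforce. All-zero fingerprints (no interactions present) are legal entries
and aggregate like any other vector.

`occ_frame` provides the classic one-vector baseline: bit set iff the
column's whole-trajectory occupancy strictly exceeds the threshold
(default 30%).

## Comparison

Within one simulation, similarity is judged by the absolute difference
count (Hamming distance) — difference matrix, histogram and link plots all
derive from it. Between simulations, where merged column spaces make raw
difference counts incomparable, the Rogers–Tanimoto similarity is used.
For 0/1 vectors it reduces to the closed form `S = 1 − 2d/(L+d)`; the
vectorised matrix routines compute `d` via inner products and apply the
closed form, and the test suite verifies them against naive
position-by-position counting and against an independent distance
implementation. The metric is pluggable in principle: any pairwise
bit-vector dissimilarity in [0, 1] can replace it (`classify` operates on
any similarity matrix).

Classification boundaries (identical ≥ 0.95; similar [0.85, 0.95);
dissimilar < 0.5) are half-open exactly as stated; similarities in
[0.5, 0.85) belong to no class. Because one fingerprint can fall in
different classes against different reference fingerprints, the
classification reports *both* pair-level counts (which partition
|A|×|B| together with the unclassified remainder) and per-side membership
counts (fingerprints appearing in ≥ 1 pair of a class, which can sum to
more than 100%). Note the geometric consequence of the closed form: on an
L-column merged space, identical-class membership at 0.95 requires
`d ≤ L/38`, so for L < 38 identical means bit-for-bit equal.

## Synthetic trajectories

The generator emulates the statistical structure the method assumes:
long blocks of a constant binding-mode fingerprint (configurable dwell
schedule, or geometric dwells with a given mean), revisited states, and
rare transient contacts — per-frame, per-column 0→1 flips lasting exactly
one frame (default rate 0; recovery tests use 0.002/frame/column).
Optional 1→0 dropouts model lost contacts. Column labels cycle through
plausible residue names and all 15 renderable interaction types so
visualisation fixtures exercise every glyph.

Default planted states form a **nested chain in single-contact steps**: a
persistent core plus one additional peripheral contact per state, with
random schedules walking only between neighbouring states. This choice is
what makes exact planted-state recovery a provable property rather than a
lucky one: every transition changes a single column, so wherever its
windowed mean crosses x₂ — noise can shift the crossing by a frame — the
filtered trajectory only ever passes through planted fingerprints. With
states differing in several columns (supplied via `states=`), noise
near a transition shifts individual columns' crossings independently and
short-lived chimeric fingerprints appear around transitions; that regime
is supported deliberately, as it reproduces the threshold sensitivity the
parameter sweep exists to expose, but exact recovery is then not
guaranteed.

What the generator does *not* model: correlated flicker between columns,
dwell-time distributions with heavy tails, gradual (multi-frame)
transitions, or any physical kinetics. Passing tests therefore demonstrate
the pipeline's correctness on block-plus-noise structure, not performance
on arbitrary real trajectories.

## Problem sizes and numerical choices

Tests and the acceptance script run on synthetic sets of 10,000 frames ×
20 columns (recovery, cross-simulation classification) and random sets of
50 × 30 (oracle equivalence), sizes at which every stage completes in
seconds while preserving the dwell/window/noise ratios of interest
(dwell ≥ 500 frames ≫ window 100; transient rate 0.002 ≪ x₂·w capacity).
Window rounding is half-to-even; binarisation and occupancy comparisons
are strict (`>`); smoothing accumulates in float64 via cumulative sums
(error far below any threshold gap at these sizes). Degenerate inputs:
empty frame sets may be loaded and written but cannot be smoothed or
aggregated (ValueError); zero-column sets are legal and merge correctly;
thresholds are validated at construction.

## Visualisation conventions

Glyph shapes map to matplotlib markers (Circle `o`, Square `s`, arrows
`v < ^ >`, ticks up/down); the two-colour vocabulary uses
Blue `#1f77b4` and Red `#d62728` as documented defaults, with matrix
heatmaps in viridis. Star layouts place the ligand at the origin and
residues on a circle ordered by residue number; coordinates persist to a
`node,x,y` CSV (full float precision via `repr`) and are reused verbatim
when loaded, so fingerprint sequences render with stable geometry. The
per-residue circular chart is a concretisation of an under-specified
figure type: angle encodes temporal position over the (expanded) frame
sequence, one ring per interaction type of the residue, arcs filled where
the interaction is present. Figure content is deterministic given inputs
and a stored layout; no randomised layout is used by default.

## Known limitations

* No fingerprint computation from coordinates; input is always a
  precomputed wide Boolean table (ProLIF-style).
* Residue-level only; atom-level fingerprints and 3D back-mapping of
  fingerprints to trajectory frames are out of scope.
* The identical/similar/dissimilar thresholds are data-set-dependent
  conventions, not calibrated probabilities.
* Cross-replicate smoothing (the default) slightly blends independent
  simulations at their junctions; use `per_replicate=True` when that
  matters.
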