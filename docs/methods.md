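# Methods

This note documents the models and procedures implemented in `fourroom`,
the defaults they use, and the choices made where the design was genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate frame and geometry

The maze is a 2 × 2 arrangement of 60 × 60 cm boxes separated by the 16 cm
depth of a door unit, giving a 136 × 136 cm footprint.  The origin is the
outer lower-left corner, axes in cm, y up.  Box labels are a declared
convention: A upper-left, B upper-right, C lower-right, D lower-left.  The
four internal doors sit at the midpoints of the shared walls; eight
door-sized "dummy" panels sit on the external walls (two per box).  Every
box centre is 38 cm from its nearest door centre, so 25 cm door disks
exclude box centres and adjacent door disks are disjoint (both facts are
asserted in tests).

Quadrant ids 1–16 are `box_index × 4 + sub_quadrant + 1`, boxes ordered
A–D, sub-quadrants row-major from each box's lower-left, half-open
boundaries (a point exactly on a centroid axis belongs to the upper/right
side; the exact centroid is therefore the upper-right quadrant).  This
fixes confusion matrices bit-for-bit across runs.

Door-gap samples have no box of their own.  For visit segmentation and
decoding truth they attach to the most recently occupied box; for quadrant
truth they go to the nearest box centroid.  The session protocol (which
door is locked, in which directions, and the 12-goal list with each box
used 3× and all four used before any repeats) is configuration, serialized
as JSON.

## Connectivity as a directed graph

Each session's lock state induces a digraph on the four boxes: edge
`u → v` iff the shared door can be pushed from `u`.  All-open states have
8 directed edges, Closed-Door test states 6, One-Way states 4 forming a
single directed cycle (validated on construction).  Door distances and
optimal first doors come from shortest paths on this graph (networkx); the
test suite checks every state/origin/goal combination against independent
path enumeration.  Locking the shared door of two adjacent boxes raises
their distance from 1 to 3 — the detour fact the behavioral scoring relies
on.

## Behavior segmentation

A *visit* is a maximal run of samples in one box.  A visit is **foraging**
iff its path length exceeds 120 cm and it covers more than 20% of the box
(10 × 10 unsmoothed grid, bins with more than one sample, i.e. ≥ 2).  Path
length is summed within non-overlapping 1 s windows anchored at the visit
start; steps straddling a window boundary are not counted (the windowing
anchor was unspecified, so it is fixed and documented here).  Samples
within 1 s of a door crossing or −2/+1 s of a door push are goal-directed
regardless of their visit; all other samples inherit the visit label.

Event cleaning: trials where the animal is already in the goal box at the
bell are rejected; pushes on doors not adjacent to the animal's box are
replaced by the first door crossed after the bell; trials missing a first
push are filled the same way; bells are never altered.

Push rates are counts per door side per minute.  The door sides locked in
C1/C2 form the "control" group in O sessions and the "locked" group in C
sessions; all other sides are "open".  First-door optimality is scored
against the set of first doors on *any* shortest path; open-session trials
at distance 2 are discarded (both doors optimal; chance 1/2 otherwise).
First-foraging is correct when the first foraging visit after the bell, in
a box other than the start box, is the goal (chance 1/3).

## Rate maps and spatial information

2 cm bins anchored to the maze geometry (not the data extent), so maps are
comparable across sessions without registration.  Samples below 5 cm/s are
removed; spikes inherit the filter of their enclosing tracking sample and
their position is linearly interpolated.  Spike and dwell maps are
smoothed separately (Gaussian, σ = 2.5 bins, 9 × 9 kernel) and then
divided; bins occupied < 0.05 s are empty.  The kernel is renormalized
over valid bins at mask edges — whether the original analysis renormalized
is unknown, so this choice is documented and covered by tests.  Whole-maze
maps are smoothed jointly; per-box maps are cut to each box's enclosing
rectangle first so smoothing cannot leak across the door gaps; 25 cm
doorway views (one per door side) are extracted from the box maps.

Skaggs information uses occupancy probabilities from the smoothed dwell
map over visited bins; zero-rate bins contribute 0; a map with zero
overall rate has SI 0.  Significance: 100 circular time shifts of the
whole spike train, uniform in [20 s, T − 20 s]; significant iff observed
SI exceeds the 95th percentile.  The place-cell classifier applies the
criteria listed in the README in the cell's highest-rate session.

## Remapping analyses

Map pairs are correlated (Pearson) over bins visited in both maps, only
when at least one map peaks above 1 Hz and ≥ 10 bins are shared.  The
individual-remapping classifier builds, per session transition, a shuffle
of 1000 random distinct-cell cross-pairings within each sequence that has
more than 10 simultaneous place cells, pooled across sequences.  The
published threshold wording ("lower than the 95th percentile") is
ambiguous; the default here flags remapping below the shuffle's **5th**
percentile — the only reading under which remapping is rarer than chance,
as reported — with the literal reading available via `bound="below95"`.
Stability is flagged above the 95th percentile.  A cell's four transition
flags encode a pattern id 0–15 (first transition = most significant bit).

The nominal 5% false-positive rate of the percentile bound applies when
the observed statistic is exchangeable with the shuffle, i.e. for cells
whose maps carry no across-session signal; the calibration test simulates
exactly that regime (`independent_sessions=True`).  For planted stable
cells the remap flag rate is ~0 under the default bound and their
stability flags are set instead — both behaviors are under test.

Rate remapping uses the Fuhs metric on zero-meaned maps over common valid
bins: 0 for identical fields (up to an additive constant), approaching 1
for disjoint ones; symmetric and bounded in [0, 1] (property-tested).  It
is intended for cells that do not spatially remap.

Cross-box analysis correlates the 6 box pairs per cell per session (4
adjacent, 2 diagonal) on separately smoothed box maps in maze coordinates
without rotation (the boxes share orientation).  Repetition shuffles
duplicate a random compartment across k ∈ {2, 3, 4} slots, the duplicates
taken from the same compartment in *different sessions* (a repeated field
sampled at different times approximates sampling it in different boxes);
remaining slots keep their own O1 maps.  Observed distributions are
compared to shuffles by two-sample KS with Holm-Bonferroni.
Foraging-vs-goal-directed stability per session uses the median observed
correlation against the 95th percentile of a within-session random-cell
shuffle.

## Place fields, bridge index, tracking

Fields are connected regions (8-connectivity by default; 4 available)
above 20% of the map maximum with area ≥ 9 bins and peak > 1 Hz, detected
on foraging-only maps; the bridge-index analysis uses whole-maze maps with
goal-directed data included so fields are not artificially split at doors.
Properties: bin-count area, rate-weighted centroid, convex hull (shapely),
mean in-field rate.  The bridge index splits a field's bins by the
infinite line through the door centre along the door axis; bins exactly on
the line count half to each side (unbiased for symmetric fields).

Overrepresentation: (i) per session, fields with centroids within 25 cm of
locked vs open doors against a 50/50 split of that total; (ii) fields near
doors vs dummy doors vs box centres against expectations proportional to
each area's surviving dwell surface (median dwell map across sessions,
bins < 0.01 s discarded); Holm-Bonferroni across sessions.

Field tracking clusters weighted centroids with k-means (50 restarts,
seeded); k is chosen by the gap statistic over 1..N (N = most fields in
any single session) with 100 uniform reference draws, using the
within-one-SE-of-the-global-maximum selection rule.  Between-session
centroid shifts above 60 cm (one box side) are excluded.  Door-distance
summaries use the closest 16 fields per door (Closed-Door) or the closest
8 per door side (One-Way).

## Bayesian decoding

Training rates λ come from one session's maps over its visited bins, with
a 0.01 Hz floor inside the likelihood to keep zero-rate bins finite (the
granularity and floor were open choices; decoding is at 2 cm map bins and
then mapped to quadrants).  Windows are non-overlapping τ = 300 ms
intervals anchored at session start; window speed is the mean sample speed
and windows under 5 cm/s are dropped.  The posterior is computed in the
log domain (Σᵢ σᵢ log λτ − λτ, constants dropped) and normalized to sum
to 1; it agrees with the direct Poisson product to 1e−10 on small
instances (tested).  Ties break to the lowest bin index (seeded random
optional).  Train and test sessions must differ; at least 15
simultaneously recorded place cells are required, otherwise the session is
skipped with a log entry.  The 16 × 16 confusion matrix is row-normalized;
the category summary reports the diagonal, same-quadrant-wrong-box,
same-box-wrong-quadrant and rest, with chance 1/16.

## Custom statistics and cluster QC

Chi-square of expected proportions: `X² = Σ (O−E)²/E`, df = N − 1,
upper-tail p.  Holm-Bonferroni: p values ranked ascending, cutoff
`α/(n − rank + 1)`; the first failure and all later values are set to
0.99, earlier values are returned unadjusted.  Isolation distance is the
squared Mahalanobis distance of the n_C-th closest non-cluster spike under
the cluster's mean/covariance (undefined when non-cluster spikes are
fewer); L-ratio is `Σ (1 − CDF_χ²(df)(D²)) / n_C` with df defaulting to
the feature dimension — 8 for the synthetic QC space of 2 features × 4
channels.  All match brute-force oracles to 1e−10 in tests.

## The synthetic world

The generator emulates the study conditions; its defaults *are* those
conditions where stated (50 Hz tracking, 23-minute sessions, 12 bell-cued
trials per session, five-session sequences with per-direction locking) and
field-realistic choices elsewhere, fixed once: foraging speeds 8–25 cm/s
and goal-directed speeds 35–60 cm/s (straddling the 5 cm/s analysis
filter), Gaussian fields with σ = 8 cm and peaks 2–8 Hz, 1–4 fields per
cell with probabilities (0.35, 0.30, 0.20, 0.15) so most cells have ≤ 3
fields, 15% of cells repeating a field template across `repeat_k` boxes,
no connectivity-triggered remapping by default (a knob exists), drift of
1 cm centroid jitter plus 5% log-rate noise per session, and a door-push
policy that tries a locked door on the remembered open route with
probability 0.9 decaying by `exp(−0.8)` per locked push.  Waveforms are a
two-parameter biphasic template so the width-of-waveform criterion is
exercisable.

Behavior is waypoint-based: goal-directed travel follows a randomly chosen
shortest-path door sequence at goal speed (straight segments with small
jitter through the door gaps), foraging is a random-waypoint walk inside
the goal box until the trial budget elapses.  Locked doors are never
crossed; a failed push costs a brief dwell at the door.  Spikes are drawn
by thinning a homogeneous Poisson stream at the cell's summed peak rate,
evaluating the true rate at linearly interpolated positions, so event
times are continuous.

What the generator does **not** emulate: theta rhythm and phase precession,
replay/reactivation events, speed or direction modulation of firing,
overdispersion relative to Poisson, LFP, multi-animal variability, and
tracking dropouts (the robust spline repair of missing tracking in real
data is out of scope; simulated tracking is complete).  Passing tests
therefore validate the *pipeline* — that each stage recovers what was
planted under its own model assumptions — not the biological findings.

`make_repetition_truth` provides the balanced one-field-per-box population
(with k boxes sharing the template) used by the repetition
self-consistency checks, where the planted condition is exact repetition
(drift set to 0).

## Problem sizes in the validation suite

The checks choose sizes by what each estimate needs: chance-level
calibrations use 500 cells across 10 sequences (remapping classifier) and
a 12-minute session pair giving > 2000 decoding windows; parameter
recovery uses 200-cell populations on shared 10-minute sessions (short
sessions inflate travel-time share and make cross-session dwell less
comparable, which is why 6-minute sessions are not used there); worked
arithmetic and formula fixed points are exact.  Shuffle counts follow the
analysis defaults (100 spike-shift, 1000 pair shuffles).

## Known limitations

- Visit boundaries and the 1 s path-window anchoring are declared
  conventions; other conventions would change path lengths by a few cm.
- The masked-kernel renormalization at map edges slightly raises edge-bin
  rates relative to an unrenormalized kernel; field centroids near box
  edges are biased inward by truncation of the field tail (isolated,
  central fields recover to well under one bin).
- The remapping-bound ambiguity is resolved by configuration, not
  adjudicated.
- The gap-statistic k selection is unstable for very small field sets; the
  tracking API requires ≥ 2 sessions and ≥ 2 fields and exposes the chosen
  k.
- One-Way door-side analyses assume the declared box layout; a different
  physical arrangement permutes labels but not distances.
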