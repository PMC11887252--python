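# Methods

This note records the models, conventions and numerical choices behind
`teemetrics`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Session logs

A session is one student's complete proficiency test: an ordered sequence
of view attempts, each a 10 Hz time series of the five probe control
coordinates, optionally with a logged per-sample precision fraction and a
perforation event flag. Units are fixed as centimetres (depth) and degrees
(all angles), with anteflexion and leftward flexion positive and time in
seconds from attempt start; these match clinical convention and are stated
in the CSV header comment. Angles are stored unwrapped — the writer never
folds rotation at ±180° — because wrapping would inject spurious motion
into the RAR index.

Irregular sampling is tolerated everywhere (all derivatives and averages
use actual timestamps; there is no silent interpolation); `resample_check`
reports intervals deviating from the nominal 100 ms clock by more than a
configurable fraction (default 50 %). Floats are written in
shortest-round-trip representation, so `read_session(write_session(s))`
reproduces `s` bit-for-bit; fixed-decimal formatting was rejected because
it cannot round-trip arbitrary float64 trajectories. Attempts are
contiguous `view_id` blocks; a strict timestamp reset within a block opens
a new attempt, so a re-visited view is reported as a duplicate rather than
merged.

The logged precision channel is assumed to share the 100 ms clock of the
motion channels. Analyses recompute precision from geometry by default;
`use_logged_precision` trusts the channel in the file instead.

## Probe kinematics

The esophagus centerline is a cubic spline through a small set of 3-D
control points, re-parameterized by arc length on a dense grid (4096
knots), so insertion depth equals arc length travelled. A reference normal
is parallel-transported along the curve; this avoids the frame flips that a
Frenet frame exhibits wherever curvature vanishes, and makes every frame
component continuous in depth.

The imaging plane is obtained by composing, in a fixed order: the
centerline frame at the current depth → handle rotation about the tangent →
ante/retroflexion tilt about the lateral axis → left/right tilt about the
antero-posterior axis → omniplane spin about the transducer axis. The
omniplane spin leaves the tip position fixed, consistent with its being an
electronic rotation. Flexion is modelled as pure tip re-orientation with no
translation — a deliberate fidelity limit; a real probe tip translates a
few millimetres when flexed. The composition order itself is a convention:
because expert targets are constructed through the same forward model that
scores the students, any fixed order yields a self-consistent metric. The
implementation is checked against an independent explicit
rotation-matrix oracle to 1e-9 on randomized states.

The bundled anatomy is a gentle thoracic curve (~62 cm long) with
navigable depths 20–50 cm and a perforation limit at 55 cm.

## Precision and the pass rule

Each view's ideal plane is anchored by three landmark points with
per-point tolerance limits (default 0.8 cm). The score maps the mean
tolerance-normalized perpendicular distance linearly onto [0, 1], clamped,
calibrated so that distances exactly at the limits give 0.80. The
functional form is a design choice — the simulator quantifies precision
electronically without publishing a formula — and the calibration makes
the 0.80 pass cutoff coincide exactly with the expert tolerance limits,
the only constraint available. The score is non-increasing in each
distance and invariant to landmark relabeling.

"Final precision held for at least 3 s" is read as a *trailing* window:
every sample from some index to the end of the attempt is at or above the
threshold and that window spans ≥ 3 s (with a 1e-9 s slack for float time
grids). The alternative reading — any 3-s window anywhere in the attempt —
was rejected as inconsistent with "final". A perforated attempt always
fails; a session passes only if all 16 views pass. Samples whose depth
leaves the navigable range score 0.

The bundled 16-view protocol lists each view's target control state,
tolerances, and the landmark positions as in-plane offsets from the
transducer tip; landmarks are placed through the forward model at load
time, which guarantees the 1.0/0.8 anchors exactly under any anatomy. The
target states and offsets are synthetic stand-ins — the study's actual
expert landmark coordinates are unpublished — chosen to span three
esophageal depth levels, several rotations and the full omniplane range.

## RAR index

The rapidity-and-randomity index of a coordinate over an attempt is the
sum of absolute central-difference derivative estimates,
`(s[n+1] − s[n−1]) / (t[n+1] − t[n−1])`, over interior indices. Endpoint
samples get no one-sided estimates: the central difference is undefined
there and the omitted contribution is negligible at 10 Hz. Degenerate
attempts (< 3 samples) score 0 with a logged warning. The index is
computed independently for depth, rotation and both flexions; the
omniplane angle is excluded by design. Both flexion directions are
computed and reported separately (the report flags which coordinates the
source figures analyzed). Session totals are per-view sums — attempts are
never concatenated, so no spurious inter-view derivative arises. The
central difference is blind to Nyquist-frequency alternation (a perfect
zig-zag at the sample rate scores 0); this is an inherent property of the
estimator, kept as a documented property test.

## Improvement rubric

Grades compare Test 2 to Test 1 per view on time, final precision and the
RAR total over the analyzed coordinates. The prose clauses overlap, so
they are evaluated with fixed precedence +2, −2, +1, −1, else 0, resolving
overlaps in favour of the extreme grades. All RAR thresholds ("±30 %",
"twice as bad", "not worse") are ratios to the same view's Test 1 value;
when that baseline is zero, maintenance conditions require the Test 2
value to be zero too, and deterioration conditions fire for any positive
value. −2 requires the time doubling *and* a precision or RAR
deterioration; +1's "shorter by 5–99 %" bound is inclusive at 5 %
(`t2 ≤ 0.95·t1`). "Final precision" is the mean over the terminal held
window when the attempt ends held, else the last sample. The two-expert
consensus step of the original design is replaced by this deterministic
rubric; per-student classification uses the sign of the mean grade.

## Cohort statistics

Normality is assessed by Shapiro–Wilk at α = 0.05; degenerate vectors
(n < 3 or constant) get `normal = None` and median/IQR is the preferred
summary. Quartiles use linear interpolation (type 7). Because the design
is intrinsically paired, the default comparisons are the paired t-test
(normal differences) or the Wilcoxon signed-rank test; the unpaired
two-sample procedures named in older reports remain available via
`paired=False`, and the method used is always recorded in the output.
Identical paired vectors short-circuit to p = 1 ("degenerate"). Paired
pass/fail counts use the exact McNemar test — a two-sided binomial on the
discordant pairs. No multiple-testing correction is applied; p-values are
reported raw.

## Synthetic cohorts

Each attempt is a mean-reverting (Ornstein–Uhlenbeck) search toward the
view's target control state, discretized at dt = 0.1 s with the exact
linear recursion of the Euler–Maruyama update. `gain` (1/s) controls how
fast the search converges — the time axis — and `noise` scales
per-coordinate diffusion — the RAR axis; the two are independently
tunable by construction. Attempts start from the previous view's target
state plus a random `seek_detour` offset, emulating the novice wandering
phase; once the pass threshold is first reached, residual jitter is scaled
by `settle_hold` (ability to hold a view). Attempts end at the first
moment the pass rule is met, at a perforation (drawn per attempt with
`perforation_prob`, or emergent when depth exceeds the anatomy's limit),
or at `timeout` (240 s). The omniplane is driven like the other
coordinates but never contributes to RAR. Everything is deterministic
given the seed.

Default profiles live in `data/profiles.yaml`. They were calibrated once,
by coarse search, so the default novice→trained contrast reproduces the
*direction and rough scale* of the findings the pipeline is meant to
detect — examination time shortened roughly two-and-a-half-fold, precision
up, flexion RAR down, an expert reference faster and smoother than any
trainee — and were frozen thereafter. Per-student heterogeneity is
log-normal in gain and noise. A cohort draws a Test 1 profile per student;
with probability `improvement_fraction` the Test 2 profile comes from the
trained distribution and is forced to strictly dominate the student's
Test 1 draw, otherwise it is a fresh novice draw.

What the generator emulates: 10 Hz multi-coordinate search trajectories,
per-view segmentation, skill improvement between tests, occasional
perforations, pass/fail structure, and paired-cohort shape. What it does
not: real esophageal mechanics, image-content difficulty differences
between views, learning dynamics within a session, or the actual
distributions of human probe motion (which are unpublished). Passing the
parameter-recovery tests therefore shows the *pipeline* recovers seeded
effects of this structure — not that the simulator reproduces human
trainees.

## Problem sizes and numerical conventions

The acceptance-level parameter-recovery checks use 20 seeded runs of
10-student, 16-view cohorts per condition, a scale chosen so the whole
suite runs in a couple of minutes on one CPU; the improvement condition
must classify ≥ 90 % of students improved with positive mean grade in at
least 19 of 20 runs, and the null condition (identical profile
distributions both tests) must keep the average cohort mean grade within
±0.3 — the rubric's −1 clause is a disjunction while +1 is a conjunction,
so a small negative bias under the null is expected and tolerated by that
band. Oracle equivalences (kinematics, RAR, point-plane distance) are
asserted at 1e-9; exact test statistics (signed-rank enumeration, McNemar
binomial) at 1e-12. Report JSON is written with sorted keys and no
timestamps, and the config echo omits output-location fields, so identical
seed + configuration yields byte-identical reports.

## Known limitations

Flexion without tip translation and a spline stand-in esophagus make the
kinematics qualitative; the precision functional form is one defensible
choice among several; the rubric's inequality boundaries follow one
documented reading of inclusive/exclusive thresholds; and cohort-level
conclusions from synthetic data validate the machinery, not human
learning.
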