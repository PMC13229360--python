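# Methods

This note documents the models, detection rules, numerical choices and
known limitations of `fgakit`. Everything stated here is computed by
the test suite or the example scripts; nothing is asserted beyond what
the code demonstrates.

## Coordinate conventions and data model

All analysis happens in a *walkway frame*: x anterior-posterior (AP,
positive along the walking direction), y mediolateral (ML, positive to
the subject's left), z up, origin at the walkway start. "Foot
position" always means the **heel** keypoint. Trajectories are
uniformly sampled; ingest interpolates isolated gaps of at most 5
samples linearly and refuses longer ones (the upstream pose estimator's
dropout behaviour is not standardized, so the gap policy is this
package's own and is configurable via `max_gap`).

The walkway frame is fitted from three calibration stances: the walkway
start, a point a known distance forward (default 5 m) and a point a
known distance to the subject's right (default 1 m). The forward axis
runs origin→forward; the ML axis is the right-point direction
orthogonalized against it (forward is the measurement-critical axis, so
it is taken exactly); z completes a right-handed frame. Because the
calibration distances are known, per-axis multiplicative scales correct
absolute calibration bias; scales outside [0.8, 1.2] are rejected as
failed calibrations rather than corrected. The vertical scale is
unobservable from floor-plane stances and defaults to the mean of the
two horizontal scales.

## Event detection

Foot speed is the magnitude of the AP heel velocity, low-pass filtered
at 3 Hz (all filters are 4th-order Butterworth applied
forward–backward: zero phase, so event timing is unbiased, with an
~8th-order effective roll-off). Stance phases are maximal regions with
foot speed below 0.15 m/s; above-threshold blips shorter than 0.10 s
are merged, and merged regions shorter than 0.15 s are discarded (both
debouncing windows sit far below the ~0.6 s stance and ~0.4 s swing of
ordinary walking). The footstep location is the mean heel position
over the stance — preferred over the position at the temporal midpoint
because averaging suppresses keypoint noise by roughly the square root
of the stance sample count (a midpoint-position alternative is
available via `footstep_position="midpoint"`). The midstance instant
is the temporal middle of the region.

Walking bouts are found by matched filtering: the summed |left|+|right|
AP foot speed is cross-correlated (normalized/Pearson, so template
amplitude mismatch with a slower or faster walker does not bias the
boundaries) against a synthetic gait-initiation template — 0.5 s of
quiet standing followed by two raised-cosine swing-speed pulses one
step period apart — and the bout start is reported at the template's
first swing onset. The termination template is the initiation template
time-reversed. Templates are filtered exactly like the measured
signals before matching. A peak correlation below 0.5 raises a
low-confidence error naming the failing template. The template's
shape, length and provenance are this package's construction (cadence
2.0 steps/s and speed 1.2 m/s by default, both configurable); no
standard template exists for this procedure.

Detection constants worth knowing: with tall, narrow swing pulses
(fast gait), the 3 Hz zero-phase filter leaks ~2–3% of the swing peak
into mid-stance — about 0.13 m/s at 1.2 m/s walking speed, safely
below the 0.15 m/s threshold but close enough that adding keypoint
noise can occasionally fragment a stance. The validation composition
is written to survive a missed footstep (see below).

## Spatiotemporal metrics and FGA scoring

Step length and signed step width are the AP and ML displacements
between consecutive footstep locations; step period is the
midstance-to-midstance interval. Head speed is the low-passed
derivative of the mean AP position of the ear/nose keypoints (or the
single head marker), kept signed so the return leg of a pivot is
negative. Bout summaries carry movement duration, mean signed head
speed over the bout (the primary speed measure; the
displacement/duration "stopwatch" speed is reported alongside),
maximum |head speed|, step-width statistics, and the maximum lateral
footstep excursion beyond the 30.48 cm walkway's edge (half-width
0.1524 m), measured from footstep |y| relative to the centerline fixed
by the frame — the FGA walkway is a fixed marked lane, so no path is
fitted.

Scores follow the published thresholds, all relative to the
Condition-1 ("Gait Level Surface") baseline and all editable
configuration embedded in every report:

- **Condition 2** (speed change, mean bout speed ratio): 3 above
  125%; 2 in [110%, 125%]; 1 in [105%, 110%); 0 below 105%.
- **Conditions 3/4** (head turns, *maximum* speed ratio against the
  baseline's maximum): 3 in [95%, 105%]; 2 in [90%, 110%]; 1 in
  [75%, 90%); 0 below 75%. A footstep beyond 15.24 cm outside the
  walkway caps the score at 1, mirroring the deduction structure of
  the observer-scored original. The printed rules give no bin above
  110%: this package scores such out-of-band speed changes 1,
  symmetric with the below-range treatment.
- **Condition 5** (pivot turn): 3 under 3 s, 2 up to 4.5 s, 1 beyond,
  0 incomplete. The turn is bracketed from head kinematics (the most
  reliably tracked keypoints): last instant forward speed ≥ +0.2 m/s
  before the global AP-position maximum to the first instant ≤
  −0.2 m/s after it.
- **Condition 6** (obstacle): clearance is the highest swing apex
  minus the median apex of the other swings; "high" clearance defaults
  to ≥ 0.10 m (the rules name the distinction without a number — this
  is a documented default, not a claim). 3 high clearance with speed
  above 75% of baseline, 2 low clearance above 75%, 1 at or below
  75%, 0 incomplete.

Interval endpoints shared by two printed bands resolve by a half-open
convention: bands are inclusive at their lower bound, the higher
score's band owns a shared endpoint, and the highest applicable score
wins. Conditions 1 and 7–10 are reported with metrics but no score —
no quantitative rules exist for them. Whether Condition 2 should use
mean or peak speed is not specified anywhere; mean is primary and peak
is reported in the metrics block.

## Two-system agreement

For simultaneous markerless (30 Hz) and marker-based (240 Hz)
recordings: the markerless summed foot speed is linearly interpolated
to 240 Hz and the clock lag recovered as the argmax of the normalized
cross-correlation over ±2 s (verified in tests against an exhaustive
all-shifts search). Space is registered by translating the markerless
stream so both left feet coincide at the first aligned sample.
Footstep *events* are then paired greedily by nearest midstance time
(within 0.3 s), and each system's step vectors are computed between
consecutively paired footsteps — so a footstep missed by one system
lengthens the same step in both streams instead of pairing a double
step against a single one; unmatched footsteps are reported, never
dropped. Pooled metrics go through OLS (markered regressed on
markerless, t-based 95% CIs) and Bland–Altman (markerless − markered;
limits at ±1.96 sample SD, no repeated-measures correction).

## The synthetic gait generator

The simulator exists to give every stage exact ground truth; its
defaults are the study conditions of the test suite.

Each heel advances in discrete swings with a raised-cosine AP
displacement profile — C¹, bell-shaped swing speed, *exactly* zero AP
velocity during stance. Gait starts and ends in a staggered stance
(feet one step length apart), so every swing advances two step lengths,
ground-truth footsteps are spaced exactly one step length apart, and
gait initiation is the exact time-reverse of termination (which is what
makes the reversed-template contract exact on simulated data). Heels
hold lateral lanes at ±step_width/2; swings lift in a sin² arc
(default apex 5 cm; an obstacle-crossing step raises one apex). The
head is the analytic midpoint of the heel paths at constant height,
with rigid ear (±8 cm ML) and nose (+10 cm AP) offsets that rotate
smoothly through pivot turns — kept closed-form rather than filtered so
the same continuous motion can be sampled at any rate and clock shift,
which is what makes paired-system simulations and the imposed-lag
ground truth exact. Keypoint noise is i.i.d. Gaussian per axis per
sample. Quiet-standing pads (1.5 s) bracket every bout.

Defaults: step length 0.6 m, step width 0.10 m (0.25 m for the "wide"
condition), cadence 2.0 steps/s, stance fraction 0.6, 30 Hz markerless
/ 240 Hz markered sampling, 6 m walkway. Cadence and stance fraction
are conventional round numbers for healthy adult gait — the protocol
this emulates does not state its subjects' values. Walking speed is
always derived (step length × cadence), never free, so spatial and
temporal parameters cannot contradict each other.

Pivot trials compose an outbound walk, a turn of the requested
duration during which both feet share a small (8 cm) forward sin²
excursion — giving the head AP position a unique interior maximum
while speeds stay near zero — and a mirrored return walk with
anatomical lanes swapped. The analytic-midpoint head makes the
simulated head speed oscillate within each stride (between ~0 at
double support and ~2× the walking speed at mid-swing) rather than
move smoothly as a real head does; mean and maximum speeds behave
correctly in ratio terms, which is what the scoring consumes.

### What passing tests do and do not show

The generator reproduces the *structure* the detectors rely on
(stance/swing alternation, bell swing pulses, quiet pads, two-system
clock lag) but not: pose-estimator artifacts with heavy-tailed or
temporally correlated errors, occlusion dropouts, soft-tissue or
headband marker motion, curved walking paths, or genuinely variable
step timing. Passing recovery tests therefore demonstrates the
pipeline's correctness and noise behaviour under Gaussian jitter, not
its field accuracy on real video-derived keypoints.

## Numerical choices and problem sizes

- Butterworth order 4, zero-phase; requested cutoffs at or above 90%
  of Nyquist are clamped with a warning (a 25 Hz keypoint-smoothing
  request cannot apply at 30 Hz sampling; the keypoint-smoothing
  cutoff is exposed as configuration).
- Derivatives are central differences (exact for quadratics at
  interior samples), one-sided at the ends.
- Resampling is linear interpolation; 240 Hz is an exact multiple of
  30 Hz, so downsampling a paired recording reproduces the slower
  stream to machine precision.
- Normalized cross-correlation windows with near-zero variance score
  zero instead of dividing by ~0.
- Stances are attributed to a bout when they start within 0.25 s of
  its boundaries: standing periods start at the recording edges and
  are thereby excluded, while the last footsteps — whose stances merge
  into terminal quiet standing — are kept.
- Test problem sizes: the noiseless recovery grid is 3×3×3 parameter
  combinations of one 4.5 m walk each; the noisy studies use 50 seeds
  at 3 mm keypoint noise (walks for localization, paired 30/240 Hz
  recordings for the agreement study, with step length drawn from
  0.4–0.7 m and alternating normal/wide widths so the pooled
  regression has real predictor spread). The full suite runs in a few
  seconds on one CPU.

## Known limitations

- Bout detection assumes one straight bout per recording; on pivot
  trials it brackets the outbound leg (turn detection runs on the full
  recording and is unaffected), so step metrics of the return leg are
  not included in pivot summaries.
- Conditions 1 and 7–10 are never scored automatically; Condition 1's
  own categorical score in particular requires observer judgments with
  no published quantitative rule.
- The turn detector requires a speed reversal; very slow pivots whose
  return speed never reaches 0.2 m/s are reported incomplete rather
  than mistimed.
- Heel-strike/toe-off sub-phase timing, treadmill data, and
  stride-variability indices are out of scope.
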