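# Methods

## The problem

A sitting pivot transfer (SPT) is the seated lateral transfer between two
surfaces — wheelchair to bed, bench to bench — that people with spinal cord
injury perform dozens of times a day, loading the shoulders, elbows and
wrists heavily each time. Biomechanical analyses of the task need a common
segmentation of the movement before trials, subjects and studies can be
compared. `sptphase` implements an automated, relative-threshold
segmentation of an SPT into four phases — **pre-lift**, **upper-limb
loading**, **lift-pivot** and **post-lift** — from two kinds of synchronized
recordings: vertical reaction forces under the trailing hand and under the
initial and target seats, and the 3D trajectory of a skin marker on the C7
spinous process (trunk movement).

## Event rules

Five event markers bound the four phases. All thresholds are *relative* —
fractions of per-trial channel maxima or multiples of per-trial baseline
variability — so detection is invariant to force-plate gain, subject weight
and marker-frame placement. Writing `speed` for the norm of the time
derivative of the filtered C7 trajectory:

| marker | rule |
|---|---|
| E1 pre-lift start | `speed` exceeds (baseline mean + 2 SD) for > 0.5 s |
| E2 loading start | trailing-hand force exceeds 5% of its whole-trial maximum for > 0.5 s |
| E3 lift-pivot start | initial-seat force falls below 5% of its maximum for > 1 s |
| E4 post-lift start | target-seat force exceeds 5% of its maximum for > 1 s |
| E5 end of transfer | target-seat force has stabilized: remains within 2 SD of the post-lift mean |

The baseline for E1 is the first 20 frames of quiet sitting. "For more than
*h* seconds" is implemented as a run of `ceil(h*fs)` consecutive frames
strictly beyond the threshold; windows truncated by the end of the recording
do not qualify. Events are searched sequentially, each rule starting
strictly after the previous marker, which guarantees E1 < E2 < E3 < E4 < E5
by construction; a rule that cannot fire raises an error naming the event,
so batch runs can triage failures.

Two readings of the E1 rule are possible (a band on the C7 *speed* vs. a
band about the starting *position*); the speed reading is used because it
makes the rule self-consistent with the quantity being thresholded and with
the persistence requirement.

### The end rule

E5 is circular as stated: the post-lift mean/SD require the phase boundary,
and the boundary requires the statistics. `resolve_end` resolves it with a
suffix-window scan: E5 is the first frame `f > E4` whose window
`[f, end of trial]` (at least 1 s long) looks like stationary quiet sitting,
meaning

1. every sample lies within `mean ± band` of the window, and
2. the fitted linear trend over the window is negligible
   (`|slope| × window length ≤ band`),

with `band = max(2·SD_window, 4·SD_baseline, 0.0125·channel max)`. The
trend guard is what makes a force that never settles (a ramp continuing to
the end of the recording) fail everywhere: a uniform ramp keeps all samples
within ±2 SD of its own mean, so the band condition alone cannot reject it.
The two floors make the all-samples condition robust: the baseline-SD term
absorbs the expected extreme-value exceedance of a ±2 SD band under
measurement noise (the maximum of ~30 effective samples sits at 2.4–2.6 SD),
and the relative term (1.25% of the seated load) absorbs the exponentially
decaying remnants the zero-phase filter leaves after a transition. Both
floors scale with the data, so gain invariance is preserved. With zero
noise and an exactly constant plateau the scheme reduces to the plain fixed
point and returns the first plateau frame exactly.

A small absolute floor (default 5 mm/s, configurable) also applies to the
E1 threshold: with noise-free kinematics the baseline SD is exactly zero and
the acausal leakage of zero-phase filtering would otherwise trigger E1 at
frame 0. 5 mm/s is far below voluntary trunk movement.

## Preprocessing

Forces are recorded at 600 Hz, kinematics at 60 Hz. Conditioning follows
standard movement-lab practice:

* **Zero-lag Butterworth low-pass.** "Fourth order, zero lag" is
  interpreted as a 2nd-order design applied forward and backward
  (`scipy.signal.sosfiltfilt`) — effective 4th-order magnitude, exactly zero
  phase; a config flag selects full-order-per-pass instead. Cutoffs: 10 Hz
  (forces), 6 Hz (kinematics). Reflective padding of 3× the filter's
  characteristic length protects the 20-frame baseline from startup
  transients; series shorter than the padding are rejected rather than
  filtered badly.
* **Exact-factor decimation.** Filtering precedes decimation; the 600→60 Hz
  step keeps every 10th sample starting at index 0 and refuses non-integer
  factors (no interpolating resample in the core path).
* **C7 speed.** Positions are filtered, then differentiated with central
  differences (one-sided at the ends), then the per-frame Euclidean norm is
  taken. Filtering positions before differentiating (rather than the
  reverse) is the choice made here; at these cutoffs the difference is
  negligible.

Everything ends up on one 60 Hz grid; frame indices are 0-based and event
times are `frame/fs`.

## Phase statistics

Durations are differences of consecutive marker times; the total cycle is
E5−E1; relative durations are computed on unrounded seconds (display
rounding is cosmetic only) and sum to 100% by construction. Cycles can be
time-normalized to 100 points (linear interpolation by default, cubic by
option) for ensemble averaging. Trial-to-trial stability of the detector is
assessed with a dependent-samples Student t-test per phase
(`t = mean(d)/(sd(d)/√n)`, n−1 df, α = 0.05); a zero-variance difference
vector is reported as a flagged degenerate case (t=0, p=1 when identical;
t=±∞, p=0 for a pure constant shift) rather than an exception. Cohort
summaries compute per-subject two-trial averages first, then group mean/SD,
mirroring the standard reporting layout.

## Synthetic trials

The generator exists so the whole pipeline is testable without recorded
data. One trial is built from a support-force budget closed to body weight
at every instant: initial seat + target seat + trailing hand + leading hand
= body weight (the leading hand is modelled for closure but not exported,
since the detector does not use it). Quiet sitting puts ~99% of weight on
the initial seat and ~1% on the resting hands; a smoothstep hand-off moves
weight onto the hands (trailing share 35%), the lift-pivot carries the body
entirely on the hands, and a second transition loads the target seat to 92%
of body weight. White Gaussian noise is added to forces at 600 Hz *before*
filtering (the preprocessing chain then shapes it as it would shape real
plate noise) and to marker coordinates at 60 Hz. The C7 marker is exactly
static during the baseline, then moves along a fixed 3D direction with a
speed profile that rises within ~70 ms of movement onset, stays high through
the transfer and decays after landing; the path length is the configured
amplitude (default 0.45 m).

**Ground truth is anchored to the detection thresholds.** Transitions are
smoothsteps whose anchors are placed so the ideal noise-free channel crosses
5% of its maximum exactly at the nominal event time (and the target seat
reaches its plateau exactly at E5). Recovering the encoded times therefore
tests that filtering, decimation and the persistence logic do not displace
events — which is what the generator is for. The target-seat settle blends
30% linear into the smoothstep so the force arrives at its plateau with a
nonzero terminal rate; a zero-slope approach makes the stabilization instant
intrinsically ambiguous.

Key defaults, with reasons:

* `body_weight_N = 773` (a 78.8 kg adult), `baseline_s = 1.0` (covers the
  20-frame detector baseline with margin), `tail_s = 1.5` (exceeds the 1 s
  end-rule window).
* `noise_sd_N = 2.0` per 600 Hz sample (typical instrumented-seat noise;
  ~0.4 N after the 10 Hz chain) and `marker_noise_sd_m = 1e-4` (active
  optical markers are sub-millimetre).
* `ramp_s = 0.035`: smoothness scale of fast transitions. Its triple,
  0.105 s, is the validity floor for sampled phase durations — transitions
  shorter than the settling scale of a 10 Hz zero-phase filter are not
  resolvable by the measurement model and are not generated.
* `trailing_share = 0.35`: plausible trailing-hand share of the hand-borne
  load; only relative shape matters to the detector (verified by the gain-
  invariance tests).

Cohorts sample per-subject mean durations per phase from truncated normal
distributions (floor 0.105 s) whose parameters are **moment-matched** so the
sampled distribution has exactly the requested mean and SD — plain
truncation would inflate the mean of the short phases. Defaults are typical
adult values: 0.74 (0.29), 0.28 (0.13), 0.72 (0.24), 0.27 (0.14) s. Each
trial adds within-subject jitter sized for a trial-to-trial correlation of
0.8 (per-trial SD = between-subject SD/√0.8, consistent with per-trial
spreads being larger than the spread of two-trial averages); the true
correlation in repeated transfers is unreported, so it is exposed as a
parameter. The moment-matched family cannot represent SDs above ~97% of
(mean − floor) (its exponential limit); such requests are rejected
explicitly.

### What the generator does *not* emulate

No impact transients at landing (real seat contact has >10 Hz content), no
pauses or multi-peaked hand loading, no left-leading or aborted transfers,
no marker occlusion bursts during movement, no inter-phase correlation
structure beyond the shared subject effect, and the C7 path is a straight
line (the detector only uses speed, which is path-shape invariant). Passing
the recovery tests therefore shows the pipeline is correct under the stated
signal model, not that the thresholds are clinically optimal for every
population.

## Numerical behaviour and known limitations

* Under defaults, detection biases are systematic and small: E1 ≈ 1 frame
  early (zero-phase filtering acausally smears movement onset backward),
  E2–E4 ≈ +0.5 frame (the first frame *strictly* beyond a threshold is the
  ceiling of the continuous crossing), E5 ≈ unbiased. Net per-phase bias is
  below 1.5 frames (25 ms) — an order of magnitude below between-subject
  SDs.
* Event timing cannot be sharper than the filter chain: a 10 Hz zero-phase
  filter settles over ~0.1 s, which is why the end rule carries a relative
  stability floor and the generator refuses sub-0.105 s phases.
* The detector assumes a single right-going transfer with the instrumented
  trailing hand; transfers back, multi-transfer recordings and mirrored
  channel roles are out of scope (channel mapping at I/O level covers
  mirroring).
* Occlusion handling is deliberately conservative: runs of ≤3 missing
  kinematic frames are linearly interpolated with a warning; longer runs are
  an error rather than a guess.
* Desk-scale problem sizes are used throughout testing: cohorts of 35
  subjects × 2 trials (~4.7 s of recording per trial), 100-trial recovery
  batches, and 1000 replicate cohorts for the t-test calibration; each runs
  in seconds on one core.
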