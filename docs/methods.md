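# Methods

This note documents the models, numerical choices and design decisions
behind the package, and what the simulation does and does not establish
about real home-cage training data.

## Protocol state machines

The protocol layer is a faithful transcription of the published training
logic of autonomous home-cage systems into deterministic state machines.
All printed constants are named module-level values with the published
defaults: epoch durations (sample 1.3 s = 0.2 s pole travel + 1.0 s
presentation + 0.1 s into retraction; go cue 0.1 s; response window 1.5 s;
ITI 2.5 s), error timeouts (2 s directional, 4 s afterwards), the
head-fixation ramp (3 s start, +2 s per 20 time-up releases, hard clamp at
10 s, completion at 30 s, post-task extension to 60 s), release thresholds
(−1/30 g start, ±2 g adaptation on the last 20 fixations when the
self-release fraction leaves (5%, 90%)), stage criteria (70%/30 trials,
75%, delay ramp 0.3→1.3 s in 0.2 s steps per 70% pass), the four
auto-assist rules, the reversal rule (>80% over 100 trials, strict) and the
photostimulation schedule (10% of trials, 1.3 s 40 Hz with a 100 ms offset
ramp, masking flash on every trial).

Choices we had to make where the protocol leaves room:

- **Criterion windows are consecutive, non-overlapping blocks** (30 scored
  trials; 100 for reversal), checked once per full block and reset whether
  or not the criterion passed.  Re-checking a sliding window after every
  trial performs hundreds of correlated tests and lets chance streaks
  advance the stages long before performance is sustained; block assessment
  keeps the per-block false-pass probability at its nominal binomial value.
  Windows also reset after every stage change, delay increment or
  contingency flip, so one streak cannot trigger two advancements.
- **Ignore trials** (no lick within 1.5 s of the go cue) are excluded from
  all performance windows and break consecutive-error runs.
- **Boundary conventions.**  A lick exactly at the go cue is pre-go (the
  choice window is the half-open interval (go, go+1.5]).  The spike-width
  cell-class boundary is strict (<0.55 ms is fast-spiking; exactly 0.55 ms
  is pyramidal).  The reversal criterion is strict (81/100 flips, 80/100
  does not).  "Duration reached 30 s" means ≥30 s: the 3,5,…,29,31
  schedule has no exact 30, so completion occurs at 31 s after exactly
  280 time-up releases.
- **Photostimulation duration is fixed at 1.3 s** from the start of its
  epoch.  Assigned to a short training delay it overruns into the response
  epoch; the overlap is kept and visible in the timeline rather than
  truncated, since the stimulus waveform has a fixed length.
- **Threshold adaptation floor**: the release band never narrows below
  10 g, preventing degenerate or inverted bands under long runs without
  self-releases.  Escapes count as non-self releases in the 20-event
  adaptation buffer.
- **Error timeouts** are appended between the response epoch and the ITI.
- **Auto-assist details** not fixed by the published rules: the lickport
  moves in 1 mm steps toward the worse-performing side; the reweighting
  rule maps the last-30-trial accuracy gap Δ to
  p(worse type) = 0.5 + 0.5·min(0.3, Δ); the free reward primes the correct
  spout of the next trial of the failing type.  Assists run during the
  discrimination and delay stages and are switched off during optogenetic
  testing.
- Time is event-driven with a 0.1 ms quantization grid, mirroring the
  precision of an embedded task controller.

## The generative agent

No generative model of mouse behavior is published for this task; the agent
is an artifact of this package, and its parameters are design choices, not
estimates of real mice.  It exists so that the protocols run closed-loop
and so the analyses have data whose ground truth is known.

The choice policy is logistic on ±1-coded inputs:

    P(left) = σ( w_stim·S₀ + w_ch·A₁ + w_wsls·A₁R₁ + b )

with a lapse rate (default 0.05) mixing in uniform choices and an ignore
rate (0.02).  `w_stim` follows a delta rule (rate 0.02 per scored trial)
toward a sigmoid-scheduled asymptote (maximum 3, midpoint 6000 scored
trials, scale 1000) whose **sign tracks the current contingency** — one
mechanism thus produces both the slow initial acquisition and the faster
re-learning after each contingency reversal.  `w_ch` (1.5 → 0.2) and
`w_wsls` (2.5 → 0.3) decay along the same sigmoid.

The win-stay-lose-switch term is essential, not decorative: a purely
perseverative policy (positive `w_ch` alone) cannot pass the
directional-licking stage, because after each 3-correct block switch it
keeps licking the now-unrewarded spout and accuracy saturates near 40%.
Lose-switch behavior — which is also the early strategy observed in real
training data — is what makes block training work.  The schedule midpoint
and scale were chosen once so that sustained ≥70% correct is reached within
roughly 5,000–20,000 trials, the scale reported for real home-cage
training; they are defaults, not fits.

A consequence worth knowing: with the published stage criteria, an
anti-perseverative agent can clear the discrimination and delay criteria on
assist-aided streaks before its stimulus weight has grown.  The closed-loop
runner therefore tracks **protocol completion** and **criterion
performance** (≥70% over the last 200 scored trials) as separate events and
runs until both have occurred, which mirrors the empirical observation that
performance fluctuates while delays are introduced and climbs afterwards.

Engagement: inter-fixation intervals are a two-component exponential
mixture (within-bout scale 1 s with probability 0.85; between-bout scale
1800 s), multiplied by `error_ifi_multiplier` (default 1.5) after
error-ending fixations — so the after-error/after-correct mean IFI ratio
equals the multiplier exactly, giving the IFI analysis a closed-form
target.  A fixed fraction of fixations (0.67) is labeled dark-cycle.
Struggling is a Poisson process (0.02 /s) whose excursions cross a release
threshold with probability exp(−margin/15 g), margin being the distance
from the resting load (10 g) to the nearer threshold; widening the band
therefore genuinely lowers the self-release hazard, which is what the
adaptive threshold controller needs to converge.  Escapes occur with
probability 0.05 within the 0.2 s clamp window.

Photostimulation effects are per (region, epoch) policy modifications: an
additive logit bias and/or a multiplicative attenuation of the stimulus
weight, applied on stimulated trials only, with learning frozen during
optogenetic testing.

What the agent does **not** model: licking kinematics, whisker mechanics,
satiation dynamics beyond engagement mixing, circadian structure beyond the
dark/light label, and any biophysics of photoinhibition.  Passing tests on
agent data shows the algorithms are implemented correctly and calibrated
under known ground truth; it does not validate the agent as a model of
mice.

## Choice-strategy regression

Regressors per scored trial: S₀ (current stimulus, +1 = lick-left
-instructing pole), S₁₋₅/A₁₋₅/R₁₋₅ (histories over scored trials), S_avg
(mean stimulus over the last 20 scored trials), WSLS = A₁·R₁, and a bias.
Rows exist only for trials with ≥20 scored predecessors.  Ignore trials
contribute no row and no history entry — history regressors refer to the
last trials on which the animal actually chose.  Analyses of closed-loop
logs start at the discrimination stage, because the directional stage's
block structure induces trivial choice-history dependence.

Fitting maximizes the Bernoulli likelihood with an L2 penalty ε = 10⁻⁴ on
the non-bias weights (intercept unpenalized) to stabilize separable
windows; the optimizer is scikit-learn's lbfgs and the result is
deterministic for a given design.  A one-class response window returns a
bias-saturated fit with a warning flag.  Prediction is left iff
P(left) > 0.5.

Cross-validation uses nine 60-trial test blocks per 500-trial window, with
starts evenly spaced over the usable range and 20-trial guard zones
excluded from training on both sides of each block.  The published recipe
("5-fold", nine repeats, 60-trial blocks, 400 training trials in a
500-trial window) is internally over-constrained — nine disjoint 60-trial
blocks exceed 500 trials, and 500 − 60 − 40 leaves at most 380 training
rows — so evenly spaced, possibly overlapping blocks with all eligible
training rows is our resolution.  The guard property (no training trial
within 20 trials of any test trial) is asserted exhaustively in the tests.

The partial-model test zeroes one fitted weight (no refit) and resamples
the pooled test-set correctness indicators 1000×; p is the fraction of
resamples where the partial model predicts strictly better.  Because the
comparison is discrete, ties are common, and the strict rule degenerates to
p = 0 for a regressor whose column never changes a prediction.  We report
both the strict p and a mid-p (ties counted half) side by side; calibration
suites use the mid-p, which rejects a true-null regressor at roughly the
nominal 5% under the simulated conditions.  A regressor is "relied upon"
when significant in ≥5 consecutive windows.  The shuffle control permutes
choices only, leaving every regressor column (built from the original
history) byte-identical.

## Nested bootstrap

The photostimulation effect is each mouse's performance change (photostim −
control, percentage points, sessions pooled) averaged unweighted across
mice; a day (dark + light) of home-cage data is one session.  Each of the
10,000 resamples redraws mice with replacement, then sessions within each
drawn mouse, then trials within each drawn session; the one-tailed p is the
fraction of resamples whose effect sign opposes the observed one.  Trial
resampling is implemented as a multinomial draw over each session's
(condition × outcome) category counts — distributionally identical to
drawing trial indices with replacement and vectorizable — and every drawn
copy of a mouse or session receives an independent lower-level resample.
Mice lacking scored trials in either condition are dropped with a warning;
with one mouse and one session the procedure reduces to a plain trial
bootstrap.  Under the simulated null (5 mice × 3 sessions × 200 trials,
identical conditions) the test rejects at ≤8% at α = 0.05, slightly
anti-conservative as expected with five resampled mice, and detects a
20-point deficit essentially always.

## Ephys metrics

Units are classed by the trough-to-peak width of the mean spike waveform
(<0.55 ms fast-spiking, otherwise pyramidal; subcortical units left
unclassified).  The unit's baseline rate pools all sweeps (counts /0.5 s);
per intensity, the relative firing rate is the mean stimulation-window rate
(counts /1.3 s) divided by that baseline, and significance is a paired
two-tailed t-test of per-sweep stimulation vs baseline rates.  Whether the
published test paired or pooled sweeps is not fully specified; pairing was
chosen as the variant that respects sweep-level covariance.  Zero-baseline
units are flagged and excluded from ratio summaries.

## Body weight

The load platform is sampled at 20 Hz; the body-weight estimate is the
center of the tallest 0.1 g histogram bin over samples above a 5 g
on-platform floor, and requires ≥100 on-platform samples.

## Problem sizes and determinism

All randomness flows through explicitly passed numpy Generators; a
closed-loop run is bit-reproducible from its seed, and the acceptance
script derives every child seed from `--seed` via `SeedSequence`.  The test
and acceptance suites use the sizes stated above (500-trial windows,
n = 5,000 for parameter recovery with 50 replicates, 200 replicates ×
1,000 resamples for the calibration suites, 20,000-trial caps for
closed-loop runs) — sizes at which the Monte-Carlo error is comfortably
inside the asserted tolerances.

## Known limitations

- The agent's learning schedule is time-driven (trial count) except for the
  contingency-tracking delta rule; it does not implement trial-by-trial
  reinforcement learning, so assist programs influence its choices only
  through the engineered free-reward priming, not through value updates.
- Auto-assist magnitudes (lickport step, reweighting map, free-reward
  priming strength) are design choices with no published values; ablation
  studies of those rules test the protocol logic, not mouse behavior.
- The load-cell model has no mechanics: struggles are hazard draws, not
  force traces, so threshold crossings carry no waveform shape.
- The strict-rule partial-model p-value is degenerate (p = 0, tie fraction
  1) for a regressor that never changes a prediction; use the reported tie
  fraction and mid-p to recognize this case.
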