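# homecage

A closed-loop simulator and analysis stack for **autonomous home-cage
behavioral training**: voluntary head-fixation, a whisker-based
two-alternative delayed-response task, and unsupervised optogenetic testing.

Autonomous home-cage systems train mice to head-fix themselves and perform a
tactile decision task with no experimenter in the loop: a protocol
controller adapts fixation durations, task stages and assist programs to the
animal's behavior, and logs every trial, lick and fixation event.  This
package re-implements that whole pipeline in software — the protocol state
machines on one side, a generative simulated mouse on the other — so the
training algorithms and the associated statistical analyses can be
executed, tested and calibrated without hardware or animals.  It is aimed at
researchers building or evaluating autonomous training systems, and at
anyone who wants a reference implementation of the analysis methods.

## What is simulated

**Protocols** (`trial_engine`, `headfix_protocol`, `task_protocol`):

- A trial = sample epoch (1.3 s pole presentation) → delay epoch
  (0.2–1.3 s) → auditory go cue (0.1 s) → response window (1.5 s) → ITI
  (2.5 s).  The first lick after the go cue is the choice; early licks in
  the delay-enforcing stage pause 0.1 s and restart the epoch.
- Head-fixation training: lickport retraction (3 mm per 20 rewarded licks,
  out to 14 mm), advancement after 30 switch triggers, a fixation-duration
  ramp (3 s → 30 s, +2 s per 20 time-up releases; later 30 → 60 s), and
  self-release thresholds starting at (−1, 30) g that widen/narrow by 2 g
  per side when the self-release fraction over the last 20 fixations leaves
  the (5%, 90%) band.
- Task training in stages — directional licking (blocks, switch after 3
  correct) → discrimination (random types, ≥70%/30-trial criterion to
  enter, ≥75% to leave) → delay ramp (0.3 → 1.3 s, one +0.2 s step per 70%
  pass) — with four auto-assist programs (lickport shift on bias, free
  reward after 5 consecutive errors, reweighted trial types, forced repeat
  after 3 consecutive errors), contingency-reversal training (flip the
  pole→lick mapping after >80% over 100 trials), and a photostimulation
  scheduler (10% of trials, 1.3 s 40 Hz stimulus with a 100 ms offset ramp).

**Agent** (`mouse_agent`, `runner`): a logistic choice policy
`P(left) = σ(w_stim·S₀ + w_ch·A₁ + w_wsls·A₁R₁ + b)` whose stimulus weight
grows along a sigmoid learning schedule (and tracks contingency reversals
through a delta rule) while the choice-history and win-stay-lose-switch
weights decay; plus engagement (bursty inter-fixation intervals, longer
after errors), struggling (load excursions that trip the release
thresholds) and configurable photostimulation effects on the policy.

**Analyses** (`choice_model`, `stats_analysis`):

- the choice-strategy logistic regression with regressors
  S₀, S₁₋₅, A₁₋₅, R₁₋₅, S_avg (20-trial stimulus mean), WSLS = A₁·R₁ and a
  bias, fit in sliding 500-trial windows (100-trial steps);
- history-excluding cross-validation (nine 60-trial test blocks per
  window, 20-trial guard zones on both sides of each block);
- partial-model bootstrap (zero one fitted weight, resample the test set
  1000×; p = fraction of resamples where the partial model predicts
  better), shuffle controls, and the 5-consecutive-window reliance rule;
- the nested mouse → session → trial bootstrap for photostimulation effect
  sizes (one-tailed p = fraction of sign-inconsistent resamples);
- Pearson 2×2 chi-square, inter-fixation-interval analyses by preceding
  outcome, body-weight estimation from the load-cell histogram mode, and
  ephys modulation metrics (spike-width cell classing at 0.55 ms, relative
  firing rate = stimulation rate / 500 ms baseline rate, paired t-tests).

## Worked example

Simulate one mouse through the full pipeline, then fit the strategy model
on its log:

```bash
$ homecage simulate --seed 7 --out run/
5812 trials, stage trail: [(32, 'discrimination'), (5182, 'delay'), (5736, 'complete')]
>=70% correct (200-trial window) first reached at trial 5812

$ homecage fit-choice --trials run/trials.jsonl --out run/fits.json --seed 0
53 windows written to run/fits.json
```

The first and last windows of `fits.json` show the strategy shift that the
simulator is built to reproduce — early choice depends on the animal's own
recent choices and outcomes, late choice on the stimulus:

```
window     1: cv=0.863 S0=-0.03 A1=+1.06 WSLS=+1.10
window  5201: cv=0.854 S0=+1.10 A1=+0.79 WSLS=+0.83
```

A photostimulation effect analysis on a hierarchical dataset (5 mice ×
3 sessions × 200 trials, a 20-point injected deficit on the 10% stimulated
trials) with the nested bootstrap:

```bash
$ homecage opto-test --data opto.csv --seed 0 --n-resamples 10000
{
  "observed_effect_points": -19.43,
  "p_one_tailed": 0.0,
  "resample_mean": -19.41,
  "resample_sd": 4.45,
  "quantiles": {"2.5": -28.32, "50": -19.30, "97.5": -10.93}
}
```

The observed effect is the within-mouse performance change (photostim −
control, percentage points) averaged across mice; the one-tailed p-value is
the fraction of the 10,000 hierarchical resamples whose effect has the
opposite sign.

## Layout

```
src/homecage/
  trial_engine.py      single-trial state machine
  headfix_protocol.py  head-fixation training, release logic, body weight
  task_protocol.py     stages, scheduling, auto-assists, reversal, photostim
  mouse_agent.py       generative agent and synthetic-data generators
  runner.py            closed-loop orchestration
  choice_model.py      strategy regression, CV, bootstrap model selection
  stats_analysis.py    performance, nested bootstrap, chi-square, ephys
  io_logs.py           JSONL/CSV logs, manifests, resume semantics
  cli.py               command-line interface
```

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
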