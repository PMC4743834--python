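# Methods

## Selection model

The decoder is a sequential probability-ratio test on pupil-size
ratios.  Stimuli are split into two groups whose background luminance
oscillates in antiphase with period 1.25 s: a 0.5 s smooth transition
(cosine ramp by default; linear available) followed by a 0.75 s hold.
PS(i) is the median pupil size over the last 0.25 s of cycle *i*, and
PPSD(i) = PS(i)/PS(i−1).  The group that just changed bright → dark has
its likelihood multiplied by PPSD, the other divided by it; a strict
threshold T on the likelihood ratio (default 1.375, conservative 1.5)
ends each binary decision.  With more than two items, the winner is
subdivided and the accumulators restart until a single item remains.

Assumptions inherited from the design: only the *ratio* of consecutive
pupil sizes matters (so tracker units are arbitrary and slow drift
largely cancels), the attended group's brightness is the dominant
systematic influence on that ratio, and evidence from successive cycles
is treated as independent.

## Numerical choices

* **Log domain.**  Likelihoods are accumulated as log L.  The raw
  product form can under/overflow on long trials; the test suite checks
  agreement with the naive product recursion to 1e−9 relative on random
  streams.
* **Baseline and carry-over.**  The first measured cycle of a trial
  only establishes PS(i−1).  After an elimination the last PS is
  carried into the next stage (configurable), so the next cycle can
  update immediately; only the likelihoods restart.
* **Missing cycles.**  A cycle whose measurement window has fewer than
  `min_valid_fraction` (default 0.5) valid samples — blinks, or a
  fixation violation during replay — contributes no update and does not
  refresh the stored PS, so the next PPSD spans the gap.  This is
  direction-neutral.
* **Ties and caps.**  A ratio exactly at T keeps sampling (strict
  "exceeds").  `max_cycles` (default 100 per binary decision) bounds
  runtime; on hitting it the current leader is taken and the outcome is
  flagged `max_cycles`.  Leader ties break to the lower group id.
* **Sample grid.**  Cycle boundaries and measurement windows are
  resolved by rounding times onto the sample grid, identically in the
  live loop and in replay, which is what makes offline replay
  bit-identical to the live run.  Trace CSVs are written with `%.17g`
  and parsed with round-trip float precision for the same reason.
* **Partitioning.**  The winning group is split into canonical-order
  halves; the half that starts bright alternates with tree depth.  A
  seeded random-polarity policy is available.  How the original display
  split groups is not modelled beyond this.

## The synthetic participant

No generative pupil model is inherited from the experimental work; the
simulator is this package's own minimal model able to reproduce the
qualitative within-cycle physiology:

    PS(t) = baseline − gain · LP(lum(t − λ)) + Σ transients + OU(t) + ε(t)

* `lum` is the attended group's normalized luminance (0 = dark,
  1 = bright); attending nothing (e.g. after the target was eliminated)
  maps to the 0.5 gray background.
* `LP` is a first-order low-pass (time constant 0.3 s) after a dead
  time λ = 0.4 s — together they delay the light response so the pupil
  still reflects the pre-transition brightness during the transition
  and crosses over roughly 0.5–1.0 s into the cycle.
* Each transition end injects a biphasic constriction transient
  (alpha-function kernel, trough 30 units at 0.2 s after transition
  end), giving the dilate–constrict–dilate shape every cycle regardless
  of the attended group.
* `OU` is an Ornstein–Uhlenbeck drift (τ = 10 s, diffusion
  `drift_sd` = 40 units/√s) standing in for hippus and arousal;
  `ε` is white sample noise (30 units).  Blinks arrive as a Poisson
  process (15/min) and invalidate 100–300 ms of samples.
* Defaults: baseline 1000 (arbitrary tracker units), `modulation_gain`
  18.  These were calibrated once, by an SPRT drift/variance argument
  and a confirming simulation, so that a default participant lands in
  the untrained-human regime of roughly 85–90 % two-item accuracy at
  T = 1.375 (about 15–20 s per selection).  This is a package default
  describing the simulator, not an empirical claim about people.

Because that calibration fixes *per-binary-decision* accuracy near
0.88, multi-stage selections compound errors: simulated 8-item accuracy
(~0.65) is well below what trained humans reach.  Likewise untested
aspects of real data — pretrial luminance history, fatigue, attention
lapses, strategy differences, partial blinks, gaze-dependent optical
artifacts — are absent.  Passing tests therefore show the decoder's
correctness and its statistical behaviour under a plausible
physiological signal model, not human-level performance figures.

The null model (`modulation_gain = 0`, transients/noise retained) is
statistically independent of the attended item by construction, so
decoder accuracy on it must equal 1/k; this chance recovery is an
acceptance test (2000 selections per k at 50 Hz with a 20-cycle cap per
stage — with the coupling off, evidence is a symmetric random walk, so
decisions are forced by the cap; the capped leader is still exactly
symmetric with respect to the cue).

## Keyboard and metrics

The free-writing layer uses eight top-level groups — seven alphabetical
fours plus `?` and space, and a two-symbol control group (backspace,
accept) — so a character costs 3 + 2 binary eliminations and a control
symbol 3 + 1.  The simulated writer intends the next needed character
while the buffer is a prefix of the target, backspace otherwise, and
accept on completion; when the decoder picks a wrong top-level group,
the stage-2 intent falls back deterministically to that group's first
symbol (the writer must select something, then corrects).  An
erroneous `accept` ends the session early — a real failure mode.

ITR follows the Wolpaw definition in bits/min with the 0·log 0 = 0
limit conventions.  Summaries are means-of-means: per-participant mean
accuracy and mean RT first (each participant's ITR computed from those
means), then an unweighted average across participants.  The
"functional ITR" of a writing session is, by this package's definition,
the Wolpaw rate for one selection among 30 options at perfect accuracy
per useful character; other accounts exist and the choice is
configurable — no external figure is claimed to be reproduced.

Training is scored per phase on blocks of 16 selections: success at the
first block ≥ 6 with 100 % accuracy, or with ≥ 80 % on block 12; one
retry at T = 1.5 is allowed, a second failure aborts.

## Problem sizes

The test suite and `scripts/acceptance.py` use sizes chosen to make
Monte-Carlo error small while keeping runs cheap: 2000 selections per
set size for chance recovery (50 Hz sampling), 400 selections per
threshold for the monotonicity check (100 Hz), 1000 random streams for
the log/product equivalence, and a ten-participant × 48-selection
simulated study at the full 250 Hz for the summary statistics.
Individual differences in the study are drawn once per participant
(baseline uniform on 800–1200; gain and drift log-normal around their
defaults with σ = 0.25 and 0.2), mirroring the known person-to-person
variation in resting size, modulation depth and fluctuation level.

## Known limitations

* The pupil model is phenomenological; it has no iris biomechanics, no
  luminance-dependent gain saturation, and no mental-imagery effects.
* Fixation violations are detected on the exported trace during
  replay; the live simulator never produces them (gaze jitter sd 0.2°),
  so pause bookkeeping (whether paused time counts toward RT, config
  flag `include_pauses_in_time`) is only exercised by constructed
  fixtures.
* Display rendering, eye-tracker drivers, calibration, auditory cues
  and the gaze-stabilized display mode are out of scope; gaze
  stabilization exists only as a per-trial flag.
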