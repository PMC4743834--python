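# pupilhci

Decoding covert visual attention from pupil size, as a human–computer
interface: stimuli oscillate between bright and dark backgrounds, the
user covertly attends one of them while fixating centrally, and the
pupillary light response — which tracks the brightness of the *attended*
stimulus, not overall luminance — betrays the intended selection.  No
overt eye movement, no electrodes, no per-user training of the decoder.
The approach targets communication for locked-in patients, secure
PIN-style input, and attention training.

`pupilhci` implements the full selection pipeline as a tested library:

* **`schedule`** — the 1.25 s brightness cycle (0.5 s smooth transition
  + 0.75 s hold; 97.0 / 5.1 cd/m² on a 13.0 cd/m² background), the
  bright/dark group bookkeeping, and the 8 → 4 → 2 → 1 elimination tree.
* **`decoder`** — the online evidence accumulator (below).
* **`pupilsim`** — a generative pupil model used as a stand-in
  participant, so the closed loop is testable without human data.
* **`keyboard`** — the hierarchical free-writing layer (8 symbol
  groups; backspace / accept semantics; symbol vs useful-text
  accounting).
* **`metrics`** — accuracy, selection time, Wolpaw information-transfer
  rate, means-of-means aggregation, and the phase training criteria.
* **`io`** — plain-text trace/event formats, the fixation-loss rule
  (gaze > 2.6° from center for > 10 ms), and offline replay that
  reproduces live runs bit-identically.

## The decoder

Let PS(i) be the median pupil size during the last 250 ms of cycle *i*.
The per-cycle evidence is the proportional pupil-size difference

    PPSD(i) = PS(i) / PS(i − 1).

Each of the two stimulus groups carries a likelihood *L* (initially 1).
After every cycle, the group that changed **bright → dark** has its *L*
multiplied by PPSD (an attended darkening dilates the pupil) and the
group that changed **dark → bright** has its *L* divided by PPSD.
Cycling continues until

    L1/L2 > T   or   L1/L2 < 1/T          (default T = 1.375)

strictly, after which the higher-*L* group wins.  With more than two
items the losing group is discarded, the winner is subdivided into new
bright/dark halves, and the accumulators restart — a sequential
probability-ratio test wrapped in a step-wise elimination tree.  Raising
*T* trades speed for accuracy.  Internally the products are kept in the
log domain; equivalence with the raw product form is part of the test
suite.

## Worked example

`examples/01_simulated_session.py` runs one 16-selection block per set
size with the default synthetic participant:

```
2 items: accuracy  87.5% (chance 50.0%), selection time  19.5 s, ITR 1.41 bits/min
4 items: accuracy  75.0% (chance 25.0%), selection time  32.5 s, ITR 1.46 bits/min
8 items: accuracy  62.5% (chance 12.5%), selection time  56.6 s, ITR 1.05 bits/min
```

Accuracy is far above chance at every set size: the decoder recovers
the attended stimulus from the pupil oscillation alone.  Multi-stage
selections compound per-stage errors, so accuracy falls and selection
time grows with set size (see `docs/methods.md` for what the synthetic
participant does and does not emulate).  The other examples dissect a
single selection cycle by cycle (`02`), write a sentence on the
hierarchical keyboard with error correction (`03`), and score training
blocks and verify replay fidelity (`04`).  Each is a short narrative
script; run them with `python examples/<name>.py`.

A thin CLI wraps the same functions:

```sh
pupilhci simulate --seed 3 --n-items 8 --n-selections 16 --out-prefix run
pupilhci replay --trace run_trace.csv --events run_events.jsonl
pupilhci evaluate --records run_records.jsonl
pupilhci keyboard-sim --text "le chat dort" --seed 12
pupilhci gen-config --out pupilhci.yaml
```

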