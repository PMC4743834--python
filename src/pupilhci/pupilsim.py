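"""Synthetic pupil-trace generator and closed-loop session simulator.

The generative model stands in for a human participant.  Pupil size is

    PS(t) = baseline - gain * LP(lum(t - latency)) + transients + drift + noise

where ``lum`` is the normalized (0 = dark, 1 = bright) luminance of the
covertly attended stimulus, LP is a first-order low-pass (the sluggish
pupillary light response), each brightness transition adds a biphasic
constriction-then-recovery transient whose trough falls a fixed delay
after the transition ends (the pupillary response to visual change,
present whichever group is attended), drift is an Ornstein-Uhlenbeck
process standing in for hippus and slow arousal fluctuations, and noise
is white measurement noise.  Blinks appear as rectangular invalid gaps.

With these ingredients the cycle-averaged trace reproduces the
characteristic pattern of the recorded data: the pupil still reflects
the pre-transition brightness during the transition, crosses over
roughly 0.5-1.0 s into the cycle, and shows an overall
dilate-constrict-dilate shape within each cycle.  Units are arbitrary
tracker units; only pupil-size ratios enter the decoder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .decoder import (
    DecoderConfig,
    PupilMeasurement,
    SelectionOutcome,
    measure_block,
    run_selection,
)
from .metrics import TrialRecord
from .schedule import (
    CycleSchedule,
    DisplayConfig,
    GroupAssignment,
    ScheduleError,
    SelectionTreeState,
    luminance_at,
)

__all__ = [
    "ParticipantProfile",
    "PupilTrace",
    "attended_luminance_series",
    "simulate_trace",
    "null_trace",
    "simulate_session",
    "ClosedLoopSimulator",
    "SessionRecording",
    "oracle_selector",
]

# time constant (s) of the slow-drift OU process; not usually worth tuning
_DRIFT_TAU = 10.0
_BLINK_DURATION_RANGE = (0.1, 0.3)
_TRANSIENT_KERNEL_DURATION = 1.0


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters of one synthetic participant.

    baseline_ps
        Resting pupil size, arbitrary tracker units.
    modulation_gain
        Pupil-size change per unit normalized luminance of the attended
        stimulus (the attention-weighted light response depth).
    response_latency, response_time_constant
        Dead time and first-order time constant (s) of the light
        response; together they place the bright/dark crossover about
        0.5-1.0 s into each cycle.
    transient_amplitude, transient_peak_delay
        Depth (units) and trough delay (s, after the transition ends) of
        the per-cycle constriction transient.
    drift_sd
        Diffusion of the slow OU drift, units per sqrt(second).
    sample_noise_sd
        White per-sample measurement noise, units.
    blink_rate
        Poisson blink rate, events per minute; blinks invalidate
        100-300 ms of samples.
    """

    baseline_ps: float = 1000.0
    modulation_gain: float = 18.0
    response_latency: float = 0.4
    response_time_constant: float = 0.3
    transient_amplitude: float = 30.0
    transient_peak_delay: float = 0.2
    drift_sd: float = 40.0
    sample_noise_sd: float = 30.0
    blink_rate: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_ps > 0:
            raise ValueError("baseline_ps must be positive")
        for name in ("modulation_gain", "transient_amplitude", "drift_sd",
                     "sample_noise_sd", "blink_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("response_latency", "response_time_constant",
                     "transient_peak_delay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PupilTrace:
    """Uniformly sampled pupil-size time series with validity mask.

    ``gaze_x``/``gaze_y`` are optional gaze coordinates in degrees from
    the display center.
    """

    sample_rate: float
    samples: np.ndarray
    valid: np.ndarray
    gaze_x: np.ndarray | None = None
    gaze_y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.samples.shape != self.valid.shape:
            raise ValueError("samples and valid mask differ in length")
        for g in (self.gaze_x, self.gaze_y):
            if g is not None and len(g) != len(self.samples):
                raise ValueError("gaze series length mismatch")

    @property
    def has_gaze(self) -> bool:
        return self.gaze_x is not None and self.gaze_y is not None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def _transient_kernel(profile: ParticipantProfile, sample_rate: float) -> np.ndarray:
    """Biphasic constriction kernel; trough -amplitude at transient_peak_delay."""
    n = max(1, round(_TRANSIENT_KERNEL_DURATION * sample_rate))
    t = (np.arange(n) + 1) / sample_rate
    u = t / profile.transient_peak_delay
    return -profile.transient_amplitude * u * np.exp(1.0 - u)


class _PupilSynth:
    """Stateful sample-block synthesiser (supports streamed generation)."""

    def __init__(self, profile: ParticipantProfile, sample_rate: float,
                 rng_noise: np.random.Generator,
                 rng_blink: np.random.Generator) -> None:
        if not sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        self.profile = profile
        self.rate = sample_rate
        dt = 1.0 / sample_rate
        self.rng = rng_noise
        self.rng_blink = rng_blink
        # dead-time delay implemented as a FIFO of raw luminance samples
        self._delay = np.full(max(0, round(profile.response_latency * sample_rate)),
                              0.5)
        self._lp_alpha = math.exp(-dt / profile.response_time_constant)
        self._lp_state = 0.5  # adapted to the gray background
        self._ou_alpha = math.exp(-dt / _DRIFT_TAU)
        # exact OU step noise for diffusion drift_sd (units / sqrt s)
        self._ou_sigma = profile.drift_sd * math.sqrt(
            _DRIFT_TAU * (1.0 - self._ou_alpha ** 2) / 2.0
        )
        self._ou_state = 0.0
        self._kernel = _transient_kernel(profile, sample_rate)
        self._pending = np.zeros(0)
        self._t = 0.0  # absolute time of the next sample
        if profile.blink_rate > 0:
            self._next_blink = self.rng_blink.exponential(60.0 / profile.blink_rate)
        else:
            self._next_blink = math.inf
        self._blink_end = -1.0

    def process(self, lum: np.ndarray,
                transient_onsets: Sequence[float] = ()) -> tuple[np.ndarray, np.ndarray]:
        """Synthesise one block of samples for normalized luminance ``lum``.

        ``transient_onsets`` are offsets in seconds from the start of
        this block at which a brightness transition ends.
        """
        lum = np.asarray(lum, dtype=float)
        n = len(lum)
        p = self.profile
        # latency: shift input through the delay line
        if len(self._delay):
            ext = np.concatenate([self._delay, lum])
            x, self._delay = ext[:n], ext[n:]
        else:
            x = lum
        # first-order low-pass, state carried between blocks
        a = self._lp_alpha
        y, zf = lfilter([1.0 - a], [1.0, -a], x, zi=[a * self._lp_state])
        self._lp_state = float(y[-1]) if n else self._lp_state
        # OU drift, exact discretisation
        eps = self.rng.standard_normal(n)
        ou, _ = lfilter([1.0], [1.0, -self._ou_alpha], self._ou_sigma * eps,
                        zi=[self._ou_alpha * self._ou_state])
        if n:
            self._ou_state = float(ou[-1])
        # transients: pending tail from earlier cycles plus new onsets
        acc = np.zeros(n)
        m = min(len(self._pending), n)
        if m:
            acc[:m] += self._pending[:m]
        pending = self._pending[m:]
        for onset in transient_onsets:
            i = round(onset * self.rate)
            if i < 0 or i >= n:
                raise ValueError("transient onset outside block")
            take = min(len(self._kernel), n - i)
            acc[i:i + take] += self._kernel[:take]
            tail = self._kernel[take:]
            if len(tail):
                if len(pending) < len(tail):
                    pending = np.concatenate(
                        [pending, np.zeros(len(tail) - len(pending))]
                    )
                pending = pending.copy()
                pending[:len(tail)] += tail
        self._pending = pending
        noise = self.rng.standard_normal(n) * p.sample_noise_sd
        ps = p.baseline_ps - p.modulation_gain * y + acc + ou + noise
        valid = self._blink_mask(n)
        self._t += n / self.rate
        return ps, valid

    def _blink_mask(self, n: int) -> np.ndarray:
        valid = np.ones(n, dtype=bool)
        t0 = self._t
        t_end = t0 + n / self.rate
        # continue a blink that started in a previous block
        if self._blink_end > t0:
            j = min(n, round((self._blink_end - t0) * self.rate))
            valid[:j] = False
        while self._next_blink < t_end:
            dur = self.rng_blink.uniform(*_BLINK_DURATION_RANGE)
            i = max(0, round((self._next_blink - t0) * self.rate))
            j = min(n, round((self._next_blink + dur - t0) * self.rate))
            valid[i:j] = False
            self._blink_end = self._next_blink + dur
            self._next_blink += self.rng_blink.exponential(
                60.0 / self.profile.blink_rate
            )
        return valid


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def attended_luminance_series(
    schedule: CycleSchedule,
    attended_item: str,
    sample_rate: float,
) -> np.ndarray:
    """Per-sample normalized luminance (0-1) of the attended item's group."""
    cfg = schedule.config
    if attended_item not in schedule.assignment.item_to_group:
        raise ScheduleError(f"item {attended_item!r} not active in schedule")
    period = cfg.cycle_period
    out: list[np.ndarray] = []
    for c in range(schedule.n_cycles):
        pol = schedule.assignment_for(c).polarity_of_item(attended_item)
        i0 = round(c * period * sample_rate)
        i1 = round((c + 1) * period * sample_rate)
        t_local = np.arange(i0, i1) / sample_rate - c * period
        # grid-boundary rounding can push t marginally outside [0, period)
        t_local = np.clip(t_local, 0.0, np.nextafter(period, 0.0))
        vals = np.array([luminance_at(cfg, pol, t) for t in t_local])
        out.append(np.asarray(cfg.normalize(vals), dtype=float))
    return np.concatenate(out) if out else np.zeros(0)


def _ramp_segment(
    cfg: DisplayConfig,
    prev_level: float,
    target_level: float,
    t_local: np.ndarray,
) -> np.ndarray:
    """Normalized luminance ramping prev -> target then holding target."""
    u = np.clip(t_local / cfg.transition_duration, 0.0, 1.0)
    if cfg.ramp_shape == "linear":
        f = u
    else:
        f = 0.5 * (1.0 - np.cos(np.pi * u))
    return prev_level + (target_level - prev_level) * f


def simulate_trace(
    profile: ParticipantProfile,
    luminance_series: np.ndarray,
    transition_times: Sequence[float] = (),
    sample_rate: float = 250.0,
    gaze_jitter_sd: float = 0.0,
) -> PupilTrace:
    """Generate a full pupil trace for a given attended-luminance series.

    ``transition_times`` are the times (s, from trace start) at which
    brightness transitions end; each injects one constriction transient.
    Fully reproducible given ``profile.seed``.
    """
    rng_noise, rng_blink, rng_gaze = _spawn_rngs(profile.seed, 3)
    synth = _PupilSynth(profile, sample_rate, rng_noise, rng_blink)
    lum = np.asarray(luminance_series, dtype=float)
    ps, valid = synth.process(lum, transient_onsets=list(transition_times))
    gx = gy = None
    if gaze_jitter_sd > 0:
        gx = rng_gaze.standard_normal(len(lum)) * gaze_jitter_sd
        gy = rng_gaze.standard_normal(len(lum)) * gaze_jitter_sd
    return PupilTrace(sample_rate=sample_rate, samples=ps, valid=valid,
                      gaze_x=gx, gaze_y=gy)


def null_trace(
    profile: ParticipantProfile,
    duration: float,
    sample_rate: float = 250.0,
    display: DisplayConfig | None = None,
) -> PupilTrace:
    """Trace with the luminance coupling switched off (modulation_gain = 0).

    Transients and noise are retained and the per-cycle transitions of a
    default schedule still occur, so the trace has the full temporal
    structure but is statistically independent of any attended item.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    display = display or DisplayConfig()
    prof = replace(profile, modulation_gain=0.0)
    n = round(duration * sample_rate)
    lum = np.full(n, 0.5)
    period = display.cycle_period
    transitions = [
        c * period + display.transition_duration
        for c in range(int(math.floor(duration / period)))
        if c * period + display.transition_duration < duration
    ]
    return simulate_trace(prof, lum, transitions, sample_rate)


@dataclass
class SessionRecording:
    """Full export of a simulated session for offline replay."""

    trace: PupilTrace
    events: list[dict]
    outcomes: list[SelectionOutcome]
    targets: list[str]


class ClosedLoopSimulator:
    """Runs the decoder against the synthetic participant, cycle by cycle.

    The simulator keeps a global sample clock so a whole session maps
    onto one continuous trace; the decoder sees exactly the median-of-
    window measurements it would receive live.
    """

    def __init__(
        self,
        profile: ParticipantProfile,
        decoder_config: DecoderConfig | None = None,
        display: DisplayConfig | None = None,
        sample_rate: float = 250.0,
        rng: np.random.Generator | None = None,
        gaze_jitter_sd: float = 0.2,
        record: bool = False,
    ) -> None:
        self.profile = profile
        self.config = decoder_config or DecoderConfig()
        self.display = display or DisplayConfig()
        self.rate = sample_rate
        self.rng = rng if rng is not None else np.random.default_rng(profile.seed)
        self.gaze_jitter_sd = gaze_jitter_sd
        self.record = record
        self._global_cycle = 0
        self._trial_id = 0
        self._samples: list[np.ndarray] = []
        self._valid: list[np.ndarray] = []
        self._gx: list[np.ndarray] = []
        self._gy: list[np.ndarray] = []
        self.events: list[dict] = []
        self.outcomes: list[SelectionOutcome] = []
        self.targets: list[str] = []

    def select(self, items: Sequence[str], target: str) -> SelectionOutcome:
        """Run one complete selection with the participant attending ``target``."""
        if target not in items:
            raise ValueError("target must be among the items")
        seeds = self.rng.integers(0, 2 ** 31, size=3)
        rng_noise, rng_blink, rng_gaze = (np.random.default_rng(int(s))
                                          for s in seeds)
        synth = _PupilSynth(self.profile, self.rate, rng_noise, rng_blink)
        prev_level = 0.5  # trial starts adapted to the gray background
        cfg = self.display
        period = cfg.cycle_period
        trial_id = self._trial_id

        def provider(cycle: int, assignment: GroupAssignment) -> PupilMeasurement:
            nonlocal prev_level
            c = self._global_cycle
            t_start = c * period
            i0 = round(t_start * self.rate)
            i1 = round((t_start + period) * self.rate)
            n = i1 - i0
            t_local = np.arange(i0, i1) / self.rate - t_start
            if target in assignment.item_to_group:
                target_level = (
                    1.0 if assignment.polarity_of_item(target) == "bright" else 0.0
                )
            else:
                # target eliminated: attention falls back to the gray background
                target_level = 0.5
            lum = _ramp_segment(cfg, prev_level, target_level, t_local)
            ps, valid = synth.process(lum, [cfg.transition_duration])
            prev_level = target_level
            if self.record:
                self._samples.append(ps)
                self._valid.append(valid)
                gx = rng_gaze.standard_normal(n) * self.gaze_jitter_sd
                gy = rng_gaze.standard_normal(n) * self.gaze_jitter_sd
                self._gx.append(gx)
                self._gy.append(gy)
                self.events.append({
                    "trial_id": trial_id,
                    "cycle_index": c,
                    "t_start_s": t_start,
                    "groups": {str(g): list(assignment.items_of(g))
                               for g in assignment.group_ids},
                    "polarity_into": {str(g): assignment.group_polarity[g]
                                      for g in assignment.group_ids},
                })
            self._global_cycle += 1
            j0 = round((t_start + period - cfg.measurement_window) * self.rate) - i0
            return measure_block(ps[j0:], valid[j0:],
                                 min_valid_fraction=self.config.min_valid_fraction,
                                 cycle_index=c)

        tree = SelectionTreeState.start(
            items, policy=self.config.partition_policy,
            seed=self.config.partition_seed,
        )
        outcome = run_selection(provider, tree, self.config, cfg)
        self._trial_id += 1
        if self.record:
            self.outcomes.append(outcome)
            self.targets.append(target)
        return outcome

    def recording(self) -> SessionRecording:
        if not self.record:
            raise ValueError("simulator was not created with record=True")
        cat = (lambda xs: np.concatenate(xs) if xs else np.zeros(0))
        trace = PupilTrace(
            sample_rate=self.rate,
            samples=cat(self._samples),
            valid=(np.concatenate(self._valid) if self._valid
                   else np.zeros(0, dtype=bool)),
            gaze_x=cat(self._gx) if self._gx else None,
            gaze_y=cat(self._gy) if self._gy else None,
        )
        return SessionRecording(trace=trace, events=list(self.events),
                                outcomes=list(self.outcomes),
                                targets=list(self.targets))


_ITEM_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def simulate_session(
    profile: ParticipantProfile,
    n_items: int,
    n_selections: int,
    decoder_config: DecoderConfig | None = None,
    seed: int | None = None,
    display: DisplayConfig | None = None,
    sample_rate: float = 250.0,
    participant_id: str = "sim",
    block_index: int = 1,
    gaze_stabilized: bool = False,
    record: bool = False,
) -> list[TrialRecord] | tuple[list[TrialRecord], SessionRecording]:
    """Simulate ``n_selections`` cued selections among ``n_items`` stimuli.

    Each trial cues a uniformly random target, runs the decoder closed
    loop against the synthetic participant, and records correctness,
    cycle count and elapsed time.  Reproducible given ``seed`` (falls
    back to ``profile.seed``).
    """
    if n_items & (n_items - 1) or n_items < 2:
        raise ValueError("n_items must be a power of two >= 2")
    if n_items > len(_ITEM_ALPHABET):
        raise ValueError("too many items")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    sim = ClosedLoopSimulator(
        profile, decoder_config, display, sample_rate, rng=rng, record=record,
    )
    items = tuple(_ITEM_ALPHABET[:n_items])
    phase = {2: 1, 4: 2, 8: 3}.get(n_items, 3)
    records: list[TrialRecord] = []
    for _ in range(n_selections):
        target = items[int(rng.integers(n_items))]
        outcome = sim.select(items, target)
        records.append(TrialRecord(
            participant_id=participant_id,
            phase=phase,
            block_index=block_index,
            n_items=n_items,
            correct=outcome.selected_item == target,
            response_time=outcome.elapsed_time,
            gaze_stabilized=gaze_stabilized,
            n_cycles=outcome.n_cycles,
        ))
    if record:
        return records, sim.recording()
    return records


def oracle_selector(ratio: float = 2.0, threshold_t: float = 1.375):
    """A noise-free 'perfect participant' selection function.

    Returns ``select(items, target) -> SelectionOutcome`` in which the
    synthetic pupil always moves with the attended group's brightness:
    PS is multiplied by ``ratio`` on cycles where the target's group
    darkens and divided by ``ratio`` where it brightens, so every binary
    decision resolves for the target in the minimum number of cycles.
    """
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")

    def select(items: Sequence[str], target: str) -> SelectionOutcome:
        if target not in items:
            raise ValueError("target must be among the items")
        ps = 1000.0

        def provider(cycle: int, assignment: GroupAssignment) -> PupilMeasurement:
            nonlocal ps
            if assignment.polarity_of_item(target) == "dark":
                ps *= ratio  # attended stimulus darkens -> pupil dilates
            else:
                ps /= ratio
            return PupilMeasurement(ps=ps, cycle_index=cycle,
                                    n_valid_samples=1, valid_fraction=1.0)

        tree = SelectionTreeState.start(items)
        return run_selection(provider, tree,
                             DecoderConfig(threshold_t=threshold_t))

    return select
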