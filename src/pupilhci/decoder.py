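"""Online selection decoder driven by pupil-size oscillations.

Each stimulus group carries a likelihood accumulator L.  After every
brightness cycle the proportional pupil-size difference

    PPSD(i) = PS(i) / PS(i-1)

is computed from the median pupil size during the last part of
consecutive cycles.  The group that just changed from bright to dark
has its L multiplied by PPSD (an attended darkening dilates the pupil);
the group that changed from dark to bright has its L divided by PPSD.
Cycling continues until L1/L2 strictly exceeds a threshold T or falls
below 1/T; the higher-L group wins.  With more than two items the loser
is discarded and the winner subdivided, until a single item remains.

Likelihoods are kept in the log domain; equivalence with the raw
product form is exercised in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Iterator, Union

import numpy as np

from .schedule import (
    DisplayConfig,
    GroupAssignment,
    PartitionPolicy,
    SelectionTreeState,
    eliminate,
    flip_polarity,
)

__all__ = [
    "DecoderError",
    "PupilMeasurement",
    "LikelihoodState",
    "DecoderConfig",
    "SelectionOutcome",
    "measure_ps",
    "ppsd",
    "update",
    "decide",
    "run_selection",
]


class DecoderError(ValueError):
    """Invalid decoder input or exhausted measurement stream."""


@dataclass(frozen=True)
class PupilMeasurement:
    """Per-cycle pupil-size summary.

    ``ps`` is the median pupil size (arbitrary tracker units) during the
    measurement window; NaN when the measurement is missing (too few
    valid samples, blink, or a discarded cycle).
    """

    ps: float
    cycle_index: int
    n_valid_samples: int
    valid_fraction: float
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing and not (self.ps > 0):
            raise DecoderError(f"pupil size must be positive, got {self.ps}")

    @classmethod
    def make_missing(cls, cycle_index: int, n_valid: int = 0,
                     valid_fraction: float = 0.0) -> "PupilMeasurement":
        return cls(ps=math.nan, cycle_index=cycle_index,
                   n_valid_samples=n_valid, valid_fraction=valid_fraction,
                   missing=True)


@dataclass(frozen=True)
class LikelihoodState:
    """Per-group evidence for one binary decision.

    ``log_l`` maps group id to log L (both start at log 1 = 0);
    ``threshold_t`` is the decision threshold T on the ratio L1/L2.
    """

    log_l: dict[int, float]
    threshold_t: float = 1.375
    cycles_elapsed: int = 0
    last_ps: float | None = None

    def __post_init__(self) -> None:
        if not self.threshold_t > 1:
            raise DecoderError("threshold_t must exceed 1")
        if len(self.log_l) != 2:
            raise DecoderError("exactly two groups are accumulated")

    @classmethod
    def initial(cls, groups: Iterable[int], threshold_t: float = 1.375,
                last_ps: float | None = None) -> "LikelihoodState":
        return cls(log_l={g: 0.0 for g in groups}, threshold_t=threshold_t,
                   last_ps=last_ps)

    @property
    def log_ratio(self) -> float:
        """log(L[g_lo] / L[g_hi]) with groups in sorted id order."""
        a, b = sorted(self.log_l)
        return self.log_l[a] - self.log_l[b]

    def leader(self) -> int:
        """Group with the higher L; ties break to the lower group id."""
        a, b = sorted(self.log_l)
        return b if self.log_l[b] > self.log_l[a] else a


def measure_ps(
    trace: "PupilTrace",
    window_start: float,
    window_end: float,
    min_valid_fraction: float = 0.5,
    cycle_index: int = 0,
) -> PupilMeasurement:
    """Median pupil size over ``[window_start, window_end)`` of a trace.

    The measurement is marked missing when the fraction of valid samples
    in the window falls below ``min_valid_fraction``.
    """
    if window_end <= window_start:
        raise DecoderError("empty measurement window")
    rate = trace.sample_rate
    i0 = round(window_start * rate)
    i1 = round(window_end * rate)
    if i0 < 0 or i1 > len(trace.samples) or i1 <= i0:
        raise DecoderError(
            f"window [{window_start}, {window_end}) outside trace extent"
        )
    return measure_block(
        np.asarray(trace.samples[i0:i1]),
        np.asarray(trace.valid[i0:i1]),
        min_valid_fraction=min_valid_fraction,
        cycle_index=cycle_index,
    )


def measure_block(
    samples: np.ndarray,
    valid: np.ndarray,
    min_valid_fraction: float = 0.5,
    cycle_index: int = 0,
) -> PupilMeasurement:
    """Median-of-valid-samples measurement on a raw sample block."""
    if samples.size == 0:
        raise DecoderError("empty measurement window")
    n_valid = int(np.count_nonzero(valid))
    vf = n_valid / samples.size
    if vf < min_valid_fraction or n_valid == 0:
        return PupilMeasurement.make_missing(cycle_index, n_valid, vf)
    ps = float(np.median(samples[np.asarray(valid, dtype=bool)]))
    return PupilMeasurement(ps=ps, cycle_index=cycle_index,
                            n_valid_samples=n_valid, valid_fraction=vf)


def ppsd(ps_current: float, ps_previous: float) -> float:
    """Proportional pupil-size difference PS(i) / PS(i-1)."""
    if not (ps_current > 0 and ps_previous > 0):
        raise DecoderError(
            f"pupil sizes must be positive, got {ps_current}, {ps_previous}"
        )
    return ps_current / ps_previous


def update(
    state: LikelihoodState,
    ppsd_value: float,
    assignment: GroupAssignment,
) -> LikelihoodState:
    """Apply one cycle's PPSD to the likelihoods.

    ``assignment`` identifies the cycle's transitions: its "dark" group
    just changed bright -> dark (L multiplied by PPSD, i.e. + log PPSD);
    the "bright" group changed dark -> bright (L divided, - log PPSD).
    """
    if not ppsd_value > 0:
        raise DecoderError(f"PPSD must be positive, got {ppsd_value}")
    to_dark = assignment.group_with_polarity("dark")
    to_bright = assignment.group_with_polarity("bright")
    if set((to_dark, to_bright)) != set(state.log_l):
        raise DecoderError("assignment groups do not match likelihood state")
    step = math.log(ppsd_value)
    log_l = dict(state.log_l)
    log_l[to_dark] += step
    log_l[to_bright] -= step
    return replace(state, log_l=log_l, cycles_elapsed=state.cycles_elapsed + 1)


def decide(state: LikelihoodState) -> int | None:
    """Winning group id once L1/L2 strictly exceeds T (or < 1/T), else None."""
    a, b = sorted(state.log_l)
    diff = state.log_l[a] - state.log_l[b]
    log_t = math.log(state.threshold_t)
    if diff > log_t:
        return a
    if diff < -log_t:
        return b
    return None


@dataclass(frozen=True)
class DecoderConfig:
    """Tunable decoder parameters.

    ``max_cycles`` caps the number of cycles per binary decision; on
    reaching it the current leader is taken and the outcome flagged.
    ``carry_ps_across_stages`` keeps the last measured pupil size after
    an elimination so the first cycle of the next stage can update
    immediately; likelihoods always restart at L = 1.
    """

    threshold_t: float = 1.375
    max_cycles: int = 100
    min_valid_fraction: float = 0.5
    carry_ps_across_stages: bool = True
    include_pauses_in_time: bool = True
    partition_policy: PartitionPolicy = "canonical"
    partition_seed: int | None = None

    def __post_init__(self) -> None:
        if not self.threshold_t > 1:
            raise DecoderError("threshold_t must exceed 1")
        if self.max_cycles < 1:
            raise DecoderError("max_cycles must be at least 1")
        if not (0 <= self.min_valid_fraction <= 1):
            raise DecoderError("min_valid_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SelectionOutcome:
    """Result of one complete (possibly multi-stage) selection."""

    selected_item: str
    n_cycles: int
    elapsed_time: float
    trajectory: tuple[tuple[float | None, float], ...]
    terminated_by: str  # "threshold" or "max_cycles"
    n_eliminations: int


MeasurementSource = Union[
    Iterable[PupilMeasurement],
    Callable[[int, GroupAssignment], PupilMeasurement],
]


def _as_callable(source: MeasurementSource):
    if callable(source):
        return source
    iterator: Iterator[PupilMeasurement] = iter(source)

    def provider(cycle: int, assignment: GroupAssignment) -> PupilMeasurement:
        try:
            return next(iterator)
        except StopIteration:
            raise DecoderError(
                "measurement stream exhausted before a selection was made"
            ) from None

    return provider


def run_selection(
    source: MeasurementSource,
    tree: SelectionTreeState,
    config: DecoderConfig | None = None,
    display: DisplayConfig | None = None,
) -> SelectionOutcome:
    """Run the full measure -> PPSD -> update -> decide elimination loop.

    ``source`` is either an iterable of per-cycle measurements or a
    callable ``(global_cycle_index, assignment_into) -> PupilMeasurement``
    (the closed-loop form: the assignment passed is the polarity each
    group transitions into during that cycle).

    The first measured cycle of a trial provides only the baseline PS.
    Missing cycles advance the clock without updating the likelihoods or
    refreshing the stored PS, so the next PPSD spans the gap.
    """
    config = config or DecoderConfig()
    display = display or DisplayConfig()
    provider = _as_callable(source)

    trajectory: list[tuple[float | None, float]] = []
    n_cycles = 0
    n_elims = 0
    capped = False
    last_ps: float | None = None

    while not tree.terminal:
        assert tree.assignment is not None
        state = LikelihoodState.initial(
            tree.assignment.group_ids, threshold_t=config.threshold_t,
            last_ps=last_ps,
        )
        winner: int | None = None
        cycles_in_stage = 0
        while winner is None:
            assignment = (
                tree.assignment if cycles_in_stage % 2 == 0
                else flip_polarity(tree.assignment)
            )
            m = provider(n_cycles, assignment)
            n_cycles += 1
            cycles_in_stage += 1
            if m.missing:
                trajectory.append((None, state.log_ratio))
            elif state.last_ps is None:
                state = replace(state, last_ps=m.ps,
                                cycles_elapsed=state.cycles_elapsed + 1)
                trajectory.append((None, state.log_ratio))
            else:
                r = ppsd(m.ps, state.last_ps)
                state = replace(update(state, r, assignment), last_ps=m.ps)
                trajectory.append((r, state.log_ratio))
                winner = decide(state)
            if winner is None and cycles_in_stage >= config.max_cycles:
                winner = state.leader()
                capped = True
        tree = eliminate(tree, winner, policy=config.partition_policy,
                         seed=config.partition_seed)
        n_elims += 1
        last_ps = state.last_ps if config.carry_ps_across_stages else None

    return SelectionOutcome(
        selected_item=tree.selected_item,
        n_cycles=n_cycles,
        elapsed_time=n_cycles * display.cycle_period,
        trajectory=tuple(trajectory),
        terminated_by="max_cycles" if capped else "threshold",
        n_eliminations=n_elims,
    )
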