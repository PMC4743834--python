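"""Stimulus scheduling for brightness-oscillation selection displays.

Items (letters, symbols) are shown on circular backgrounds whose luminance
oscillates between a bright and a dark level in fixed-period cycles.  The
items are split into two complementary groups with opposite brightness
polarity; the polarity of both groups flips on every cycle.  Selection
proceeds by step-wise elimination: one group is discarded at each binary
decision and the winning group is subdivided anew until a single item
remains (8 -> 4 -> 2 -> 1 for the trained configurations).

This module owns the timing/luminance constants, the bright/dark group
bookkeeping, and the elimination tree.  It performs no rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

Polarity = Literal["bright", "dark"]
PartitionPolicy = Literal["canonical", "random"]

__all__ = [
    "ScheduleError",
    "DisplayConfig",
    "GroupAssignment",
    "SelectionTreeState",
    "CycleSchedule",
    "make_partition",
    "flip_polarity",
    "eliminate",
    "luminance_at",
    "opposite_polarity",
]


class ScheduleError(ValueError):
    """Invalid schedule configuration or request."""


def opposite_polarity(polarity: Polarity) -> Polarity:
    return "dark" if polarity == "bright" else "bright"


@dataclass(frozen=True)
class DisplayConfig:
    """Timing and luminance layout of one brightness cycle.

    A cycle of ``cycle_period`` seconds consists of a smooth luminance
    transition of ``transition_duration`` seconds followed by
    ``hold_duration`` seconds of constant luminance; pupil size is
    measured during the final ``measurement_window`` seconds.

    Defaults correspond to a 0.8 Hz oscillation between 97.0 and
    5.1 cd/m^2 on a 13.0 cd/m^2 background.
    """

    bright_luminance: float = 97.0
    dark_luminance: float = 5.1
    background_luminance: float = 13.0
    cycle_period: float = 1.25
    transition_duration: float = 0.5
    hold_duration: float = 0.75
    measurement_window: float = 0.25
    ramp_shape: Literal["linear", "cosine"] = "cosine"

    def __post_init__(self) -> None:
        if not math.isclose(
            self.transition_duration + self.hold_duration, self.cycle_period,
            rel_tol=0.0, abs_tol=1e-9,
        ):
            raise ScheduleError(
                "transition_duration + hold_duration must equal cycle_period"
            )
        if self.measurement_window > self.hold_duration:
            raise ScheduleError("measurement_window must fit inside the hold period")
        if not (self.bright_luminance > self.background_luminance
                > self.dark_luminance > 0):
            raise ScheduleError(
                "require bright_luminance > background_luminance > dark_luminance > 0"
            )
        if self.ramp_shape not in ("linear", "cosine"):
            raise ScheduleError(f"unknown ramp_shape {self.ramp_shape!r}")
        if min(self.cycle_period, self.transition_duration, self.hold_duration,
               self.measurement_window) <= 0:
            raise ScheduleError("all durations must be positive")

    def luminance_of(self, polarity: Polarity) -> float:
        return self.bright_luminance if polarity == "bright" else self.dark_luminance

    def normalize(self, luminance: float | np.ndarray) -> float | np.ndarray:
        """Map luminance to [0, 1] with 0 = dark level, 1 = bright level."""
        return (luminance - self.dark_luminance) / (
            self.bright_luminance - self.dark_luminance
        )


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of the active items into two opposite-polarity groups.

    ``group_polarity`` holds the polarity each group transitions INTO
    during the current cycle (so a group with polarity "dark" is the one
    that just changed from bright to dark).
    """

    item_to_group: Mapping[str, int]
    group_polarity: Mapping[int, Polarity]

    def __post_init__(self) -> None:
        groups = set(self.item_to_group.values())
        if groups != set(self.group_polarity):
            raise ScheduleError("item groups and polarity groups disagree")
        if len(groups) != 2:
            raise ScheduleError("exactly two groups are required")
        pols = list(self.group_polarity.values())
        if pols[0] == pols[1]:
            raise ScheduleError("the two groups must have opposite polarity")

    @property
    def group_ids(self) -> tuple[int, int]:
        return tuple(sorted(self.group_polarity))  # type: ignore[return-value]

    def items_of(self, group: int) -> tuple[str, ...]:
        return tuple(i for i, g in self.item_to_group.items() if g == group)

    def group_of(self, item: str) -> int:
        try:
            return self.item_to_group[item]
        except KeyError:
            raise ScheduleError(f"item {item!r} not in assignment") from None

    def polarity_of_item(self, item: str) -> Polarity:
        return self.group_polarity[self.group_of(item)]

    def group_with_polarity(self, polarity: Polarity) -> int:
        for g, p in self.group_polarity.items():
            if p == polarity:
                return g
        raise ScheduleError(f"no group with polarity {polarity}")  # pragma: no cover

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self.item_to_group)


def make_partition(
    items: Sequence[str],
    policy: PartitionPolicy = "canonical",
    seed: int | None = None,
    depth: int = 0,
) -> GroupAssignment:
    """Split ``items`` into two equal bright/dark groups.

    The canonical policy assigns the first half of the items (in the
    given order) to group 0 and alternates group 0's initial polarity
    with ``depth`` so that successive subdivisions do not always start
    on the same polarity.  The random policy keeps the canonical halves
    but draws group 0's initial polarity from a seeded RNG.
    """
    items = list(items)
    if len(items) == 0 or len(items) % 2 != 0:
        raise ScheduleError(
            f"cannot partition {len(items)} items into two equal groups"
        )
    if len(set(items)) != len(items):
        raise ScheduleError("duplicate item identifiers")
    half = len(items) // 2
    item_to_group = {it: (0 if k < half else 1) for k, it in enumerate(items)}
    if policy == "canonical":
        g0: Polarity = "bright" if depth % 2 == 0 else "dark"
    elif policy == "random":
        rng = np.random.default_rng(seed)
        g0 = "bright" if rng.integers(2) == 0 else "dark"
    else:
        raise ScheduleError(f"unknown partition policy {policy!r}")
    return GroupAssignment(
        item_to_group=item_to_group,
        group_polarity={0: g0, 1: opposite_polarity(g0)},
    )


def flip_polarity(assignment: GroupAssignment) -> GroupAssignment:
    """Invert both groups' polarity; membership is unchanged."""
    return GroupAssignment(
        item_to_group=dict(assignment.item_to_group),
        group_polarity={
            g: opposite_polarity(p) for g, p in assignment.group_polarity.items()
        },
    )


@dataclass(frozen=True)
class SelectionTreeState:
    """State of the step-wise elimination over the item set.

    ``assignment`` gives the polarity transitioned into on the first
    cycle of the current binary decision; it is None in the terminal
    state (a single surviving item).
    """

    active_items: tuple[str, ...]
    assignment: GroupAssignment | None
    depth: int = 0
    eliminated: tuple[tuple[str, ...], ...] = ()

    @property
    def terminal(self) -> bool:
        return len(self.active_items) == 1

    @property
    def selected_item(self) -> str:
        if not self.terminal:
            raise ScheduleError("selection tree is not terminal")
        return self.active_items[0]

    @classmethod
    def start(
        cls,
        items: Sequence[str],
        policy: PartitionPolicy = "canonical",
        seed: int | None = None,
    ) -> "SelectionTreeState":
        items = tuple(items)
        if len(items) == 1:
            return cls(active_items=items, assignment=None)
        return cls(
            active_items=items,
            assignment=make_partition(items, policy=policy, seed=seed, depth=0),
        )


def eliminate(
    state: SelectionTreeState,
    winner: int,
    policy: PartitionPolicy = "canonical",
    seed: int | None = None,
) -> SelectionTreeState:
    """Discard the losing group and subdivide the winning one.

    The new state's active items are the winner's items.  If more than
    one item survives, a fresh partition is created at depth + 1;
    otherwise the state is terminal.
    """
    if state.terminal:
        raise ScheduleError("cannot eliminate from a terminal state")
    assert state.assignment is not None
    if winner not in state.assignment.group_polarity:
        raise ScheduleError(f"group {winner} is not part of the current assignment")
    loser = next(g for g in state.assignment.group_ids if g != winner)
    survivors = state.assignment.items_of(winner)
    discarded = state.assignment.items_of(loser)
    depth = state.depth + 1
    if len(survivors) > 1:
        assignment = make_partition(survivors, policy=policy, seed=seed, depth=depth)
    else:
        assignment = None
    return SelectionTreeState(
        active_items=survivors,
        assignment=assignment,
        depth=depth,
        eliminated=state.eliminated + (discarded,),
    )


def luminance_at(config: DisplayConfig, polarity_start: Polarity, t: float) -> float:
    """Luminance (cd/m^2) of a group at time ``t`` within one cycle.

    ``polarity_start`` is the polarity being transitioned INTO during
    this cycle: for ``t`` within the transition the value ramps from the
    opposite luminance towards the target per ``ramp_shape``; afterwards
    it equals the target exactly.  By construction the trajectory is
    continuous across cycle boundaries when polarity alternates.
    """
    if not (0 <= t < config.cycle_period):
        raise ScheduleError(f"t={t} outside cycle [0, {config.cycle_period})")
    target = config.luminance_of(polarity_start)
    if t >= config.transition_duration:
        return target
    origin = config.luminance_of(opposite_polarity(polarity_start))
    u = t / config.transition_duration
    if config.ramp_shape == "linear":
        f = u
    else:
        f = 0.5 * (1.0 - math.cos(math.pi * u))
    return origin + (target - origin) * f


@dataclass(frozen=True)
class CycleSchedule:
    """A fixed run of cycles for one binary decision stage.

    ``assignment`` is the polarity transitioned into on cycle 0; the
    polarity of both groups flips on every subsequent cycle.
    """

    config: DisplayConfig
    assignment: GroupAssignment
    n_cycles: int

    def assignment_for(self, cycle: int) -> GroupAssignment:
        if not (0 <= cycle < self.n_cycles):
            raise ScheduleError(f"cycle {cycle} outside schedule")
        return self.assignment if cycle % 2 == 0 else flip_polarity(self.assignment)

    def event_record(self, trial_id: int, cycle: int, t_start: float) -> dict:
        """One JSON-serialisable event-log record for ``cycle``."""
        a = self.assignment_for(cycle)
        return {
            "trial_id": trial_id,
            "cycle_index": cycle,
            "t_start_s": t_start,
            "groups": {str(g): list(a.items_of(g)) for g in a.group_ids},
            "polarity_into": {str(g): a.group_polarity[g] for g in a.group_ids},
        }
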