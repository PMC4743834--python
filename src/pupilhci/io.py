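"""File formats, configuration, fixation-violation detection, and offline
replay of recorded or simulated sessions.

Traces travel as plain CSV (``time_s, pupil, valid, gaze_x_deg,
gaze_y_deg``), event logs and outcomes as JSON Lines, configuration as
YAML.  Gaze is expressed in degrees from the display center so the
fixation rule is display-independent.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .decoder import (
    DecoderConfig,
    DecoderError,
    PupilMeasurement,
    SelectionOutcome,
    measure_ps,
    run_selection,
)
from .metrics import TrialRecord
from .pupilsim import ParticipantProfile, PupilTrace, SessionRecording
from .schedule import DisplayConfig, GroupAssignment, SelectionTreeState

__all__ = [
    "IOError_",
    "FixationConfig",
    "read_trace",
    "write_trace",
    "write_events",
    "read_events",
    "write_outcomes",
    "read_outcomes",
    "write_trial_records",
    "read_trial_records",
    "fixation_violations",
    "replay",
    "default_config",
    "load_config",
    "save_config",
]


class IOError_(ValueError):
    """Malformed file or inconsistent replay input."""


@dataclass(frozen=True)
class FixationConfig:
    """Fixation-loss rule: gaze further than ``max_deviation`` degrees
    from the display center for longer than ``min_duration`` seconds."""

    max_deviation: float = 2.6
    min_duration: float = 0.010

    def __post_init__(self) -> None:
        if self.max_deviation <= 0 or self.min_duration <= 0:
            raise IOError_("fixation thresholds must be positive")


_TRACE_COLUMNS = ["time_s", "pupil", "valid", "gaze_x_deg", "gaze_y_deg"]


def write_trace(trace: PupilTrace, path: str | Path) -> None:
    """Write a trace as CSV; gaze columns are included only if present."""
    data = {
        "time_s": trace.times,
        "pupil": trace.samples,
        "valid": trace.valid.astype(int),
    }
    if trace.has_gaze:
        data["gaze_x_deg"] = trace.gaze_x
        data["gaze_y_deg"] = trace.gaze_y
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_trace(path: str | Path) -> PupilTrace:
    """Read a trace CSV; requires a uniform, increasing time column."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "pupil", "valid"}
    if not required.issubset(df.columns):
        raise IOError_(
            f"trace file must contain columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise IOError_("trace must contain at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise IOError_("time column must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise IOError_("trace sampling must be uniform")
    rate = (len(t) - 1) / (t[-1] - t[0])
    if abs(rate - round(rate)) < 1e-6:
        rate = float(round(rate))
    gx = gy = None
    if {"gaze_x_deg", "gaze_y_deg"}.issubset(df.columns):
        gx = df["gaze_x_deg"].to_numpy(dtype=float)
        gy = df["gaze_y_deg"].to_numpy(dtype=float)
    return PupilTrace(
        sample_rate=rate,
        samples=df["pupil"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        gaze_x=gx,
        gaze_y=gy,
    )


def _write_jsonl(records: Iterable[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def _read_jsonl(path: str | Path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def write_events(events: Iterable[dict], path: str | Path) -> None:
    _write_jsonl(events, path)


def read_events(path: str | Path) -> list[dict]:
    events = _read_jsonl(path)
    last_t = -math.inf
    for e in events:
        missing = {"trial_id", "cycle_index", "t_start_s", "groups",
                   "polarity_into"} - set(e)
        if missing:
            raise IOError_(f"event record missing fields {sorted(missing)}")
        if e["t_start_s"] < last_t:
            raise IOError_("event timestamps must be non-decreasing")
        last_t = e["t_start_s"]
    return events


def write_outcomes(outcomes: Iterable[SelectionOutcome], path: str | Path) -> None:
    _write_jsonl((dataclasses.asdict(o) for o in outcomes), path)


def read_outcomes(path: str | Path) -> list[SelectionOutcome]:
    return [
        SelectionOutcome(
            selected_item=d["selected_item"],
            n_cycles=d["n_cycles"],
            elapsed_time=d["elapsed_time"],
            trajectory=tuple((r, lr) for r, lr in d["trajectory"]),
            terminated_by=d["terminated_by"],
            n_eliminations=d["n_eliminations"],
        )
        for d in _read_jsonl(path)
    ]


def write_trial_records(records: Iterable[TrialRecord], path: str | Path) -> None:
    _write_jsonl((dataclasses.asdict(r) for r in records), path)


def read_trial_records(path: str | Path) -> list[TrialRecord]:
    return [TrialRecord(**d) for d in _read_jsonl(path)]


def fixation_violations(
    trace: PupilTrace,
    config: FixationConfig | None = None,
) -> list[tuple[float, float]]:
    """Maximal intervals with gaze continuously beyond the fixation rule.

    An interval qualifies when the Euclidean gaze deviation exceeds
    ``max_deviation`` for strictly longer than ``min_duration``.
    """
    config = config or FixationConfig()
    if not trace.has_gaze:
        raise IOError_("trace carries no gaze data")
    dev = np.hypot(trace.gaze_x, trace.gaze_y)
    beyond = dev > config.max_deviation
    if not beyond.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], beyond, [False]))
                                   .astype(int)))
    starts, ends = edges[::2], edges[1::2]
    dt = 1.0 / trace.sample_rate
    out = []
    for i0, i1 in zip(starts, ends):
        if (i1 - i0) * dt > config.min_duration:
            out.append((i0 * dt, i1 * dt))
    return out


def _itemset(event: dict) -> frozenset:
    return frozenset(s for items in event["groups"].values() for s in items)


def replay(
    trace: PupilTrace,
    events: Sequence[dict],
    decoder_config: DecoderConfig | None = None,
    display: DisplayConfig | None = None,
    fixation_config: FixationConfig | None = None,
) -> list[SelectionOutcome]:
    """Re-run every recorded selection offline from trace + event log.

    Measurements are recomputed from the trace at each recorded cycle's
    measurement window; cycles overlapping a fixation violation are
    discarded (treated as missing).  Given the inputs exported by a
    simulated session and the same decoder configuration, the outcomes
    are bit-identical to the live ones.
    """
    config = decoder_config or DecoderConfig()
    display = display or DisplayConfig()
    period = display.cycle_period
    if trace.has_gaze:
        violations = fixation_violations(
            trace, fixation_config or FixationConfig()
        )
    else:
        violations = []

    by_trial: dict[int, list[dict]] = {}
    for e in events:
        by_trial.setdefault(e["trial_id"], []).append(e)

    outcomes = []
    for trial_id in sorted(by_trial):
        recs = by_trial[trial_id]
        t_last_end = recs[-1]["t_start_s"] + period
        # compare on the sample grid: a cycle's last sample index may
        # round below t_last_end * rate
        if round(t_last_end * trace.sample_rate) > len(trace.samples):
            raise IOError_(
                f"trial {trial_id} extends to {t_last_end:.3f} s but the "
                f"trace ends at {trace.duration:.3f} s"
            )
        cursor = {"i": 0}

        def provider(cycle: int, assignment: GroupAssignment) -> PupilMeasurement:
            if cursor["i"] >= len(recs):
                raise DecoderError(
                    "event log exhausted before the selection terminated"
                )
            rec = recs[cursor["i"]]
            cursor["i"] += 1
            recorded = {
                int(g): tuple(items) for g, items in rec["groups"].items()
            }
            for g in assignment.group_ids:
                if set(assignment.items_of(g)) != set(recorded.get(g, ())):
                    raise IOError_(
                        f"recorded groups at trial {rec['trial_id']} cycle "
                        f"{rec['cycle_index']} do not match the replayed tree"
                    )
                if assignment.group_polarity[g] != rec["polarity_into"][str(g)]:
                    raise IOError_("recorded polarity does not match replay")
            t0 = rec["t_start_s"]
            if any(s < t0 + period and e > t0 for s, e in violations):
                return PupilMeasurement.make_missing(rec["cycle_index"])
            return measure_ps(
                trace,
                t0 + period - display.measurement_window,
                t0 + period,
                min_valid_fraction=config.min_valid_fraction,
                cycle_index=rec["cycle_index"],
            )

        # item ordering must match the recorded first assignment so the
        # canonical partition reproduces the live tree
        first = recs[0]
        rec_items = {int(g): tuple(items) for g, items in first["groups"].items()}
        order = [s for g in sorted(rec_items) for s in rec_items[g]]
        tree = SelectionTreeState.start(order, policy=config.partition_policy,
                                        seed=config.partition_seed)
        outcome = run_selection(provider, tree, config, display)
        if config.include_pauses_in_time:
            t_first = recs[0]["t_start_s"]
            t_end = recs[outcome.n_cycles - 1]["t_start_s"] + period
            outcome = dataclasses.replace(outcome, elapsed_time=t_end - t_first)
        outcomes.append(outcome)
    return outcomes


# --------------------------------------------------------------------------
# configuration files


def default_config() -> dict:
    """Nested dict of all tunable parameters with package defaults."""
    return {
        "display": dataclasses.asdict(DisplayConfig()),
        "decoder": dataclasses.asdict(DecoderConfig()),
        "profile": dataclasses.asdict(ParticipantProfile()),
        "fixation": dataclasses.asdict(FixationConfig()),
        "simulation": {
            "sample_rate": 250.0,
            "n_items": 2,
            "n_selections": 16,
            "gaze_jitter_sd": 0.2,
        },
    }


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise IOError_(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> dict:
    """Load a YAML config; returns dataclasses plus the simulation block."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    merged = default_config()
    for section, values in raw.items():
        if section not in merged:
            raise IOError_(f"unknown config section {section!r}")
        merged[section].update(values or {})
    return {
        "display": _build(DisplayConfig, merged["display"]),
        "decoder": _build(DecoderConfig, merged["decoder"]),
        "profile": _build(ParticipantProfile, merged["profile"]),
        "fixation": _build(FixationConfig, merged["fixation"]),
        "simulation": merged["simulation"],
    }
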