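"""Performance metrics: accuracy, response time, information-transfer rate,
means-of-means aggregation, and the training success criteria.

The information-transfer rate (ITR) of an n-alternative selection with
accuracy Acc and response time RT seconds follows Wolpaw's definition,

    ITR = [log2 n + Acc log2 Acc + (1 - Acc) log2((1 - Acc)/(n - 1))] / (RT/60)

in bits per minute.  Summary statistics are first computed per
participant and then averaged unweighted across participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MetricsError",
    "TrialRecord",
    "ParticipantSummary",
    "TrainingResult",
    "itr",
    "chance_level",
    "grand_means",
    "participant_summaries",
    "training_outcome",
]


class MetricsError(ValueError):
    """Invalid metrics input."""


@dataclass(frozen=True)
class TrialRecord:
    """One completed selection trial."""

    participant_id: str
    phase: int
    block_index: int
    n_items: int
    correct: bool
    response_time: float
    gaze_stabilized: bool = False
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        if not self.response_time > 0:
            raise MetricsError("response_time must be positive")
        if self.phase in (1, 2, 3) and self.n_items not in (2, 4, 8):
            raise MetricsError("phases 1-3 use 2, 4 or 8 items")


@dataclass(frozen=True)
class ParticipantSummary:
    participant_id: str
    n_trials: int
    mean_accuracy: float
    mean_rt: float
    itr: float


@dataclass(frozen=True)
class TrainingResult:
    status: str  # "success", "retry_conservative", "aborted"
    stop_block: int
    threshold: float


def itr(n: int, acc: float, rt: float) -> float:
    """Information-transfer rate in bits per minute.

    Limit conventions: the entropy terms use 0 * log2(0) = 0, so acc = 0
    and acc = 1 are both well defined (acc = 1 yields log2 n bits per
    selection).
    """
    if n < 2:
        raise MetricsError("n must be at least 2")
    if not (0 <= acc <= 1):
        raise MetricsError("acc must lie in [0, 1]")
    if not rt > 0:
        raise MetricsError("rt must be positive")
    bits = math.log2(n)
    if acc > 0:
        bits += acc * math.log2(acc)
    if acc < 1:
        bits += (1 - acc) * math.log2((1 - acc) / (n - 1))
    return bits / (rt / 60.0)


def chance_level(n: int) -> float:
    """Chance accuracy 1/n of an n-alternative selection."""
    if n < 2:
        raise MetricsError("n must be at least 2")
    return 1.0 / n


def _records_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "n_items": r.n_items,
            "correct": bool(r.correct),
            "response_time": r.response_time,
        }
        for r in records
    )
    if df.empty:
        raise MetricsError("no trial records")
    if df["n_items"].nunique() != 1:
        raise MetricsError(
            "records mix different n_items; aggregate one phase at a time"
        )
    return df


def participant_summaries(records: Iterable[TrialRecord]) -> list[ParticipantSummary]:
    """Per-participant mean accuracy, mean RT and ITR (from those means)."""
    df = _records_frame(records)
    n = int(df["n_items"].iloc[0])
    out = []
    for pid, sub in df.groupby("participant_id", sort=True):
        acc = float(sub["correct"].mean())
        rt = float(sub["response_time"].mean())
        out.append(
            ParticipantSummary(
                participant_id=str(pid), n_trials=len(sub),
                mean_accuracy=acc, mean_rt=rt, itr=itr(n, acc, rt),
            )
        )
    return out


def grand_means(records: Iterable[TrialRecord]) -> dict[str, float]:
    """Unweighted across-participant averages of per-participant means.

    Per-participant accuracy, RT and ITR are computed first; the grand
    values average those (a means-of-means), so participants with more
    trials do not weigh more.
    """
    summaries = participant_summaries(records)
    k = len(summaries)
    return {
        "accuracy": sum(s.mean_accuracy for s in summaries) / k,
        "rt": sum(s.mean_rt for s in summaries) / k,
        "itr": sum(s.itr for s in summaries) / k,
    }


def _evaluate_run(block_accuracies: Sequence[float]) -> tuple[bool, int]:
    if not 1 <= len(block_accuracies) <= 12:
        raise MetricsError("a training run consists of 1-12 blocks")
    for a in block_accuracies:
        if not (0 <= a <= 1):
            raise MetricsError("block accuracies are proportions in [0, 1]")
    for k in range(6, len(block_accuracies) + 1):
        if block_accuracies[k - 1] == 1.0:
            return True, k
    if len(block_accuracies) >= 12 and block_accuracies[11] >= 0.8:
        return True, 12
    return False, len(block_accuracies)


def training_outcome(
    block_accuracies: Sequence[float],
    block_size: int = 16,
    retry_block_accuracies: Sequence[float] | None = None,
    default_threshold: float = 1.375,
    conservative_threshold: float = 1.5,
) -> TrainingResult:
    """Evaluate the phase training criteria on block accuracies.

    A run succeeds at the first block >= 6 with 100% accuracy, or at
    block 12 with >= 80% accuracy.  A failed run earns one retry at the
    conservative threshold; a second failure aborts the phase.
    """
    if block_size < 1:
        raise MetricsError("block_size must be positive")
    ok, stop = _evaluate_run(block_accuracies)
    if ok:
        return TrainingResult("success", stop, default_threshold)
    if retry_block_accuracies is None:
        return TrainingResult("retry_conservative", stop, conservative_threshold)
    ok2, stop2 = _evaluate_run(retry_block_accuracies)
    status = "success" if ok2 else "aborted"
    return TrainingResult(status, stop2, conservative_threshold)
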