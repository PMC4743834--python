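"""Hierarchical free-writing keyboard.

Symbols are arranged in eight top-level groups: seven groups of four
characters and one group with the two control symbols (backspace,
accept).  Entering a symbol is a one-of-eight group selection followed
by a one-of-four selection within the group (one-of-two for the control
group), so a character costs exactly 3 + 2 = 5 binary eliminations and
a control symbol 3 + 1 = 4.

The text buffer distinguishes the symbols entered (including
corrections) from the useful text ultimately accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

from .decoder import SelectionOutcome
from .metrics import itr as wolpaw_itr

__all__ = [
    "BACKSPACE",
    "ACCEPT",
    "SPACE",
    "KeyboardError",
    "KeyboardLayout",
    "TextSession",
    "SymbolSelection",
    "default_layout",
    "select_symbol",
    "apply_symbol",
    "session_stats",
    "write_text",
]

BACKSPACE = "<backspace>"
ACCEPT = "<accept>"
SPACE = " "
_CONTROLS = (BACKSPACE, ACCEPT)


class KeyboardError(ValueError):
    """Invalid keyboard layout or session operation."""


@dataclass(frozen=True)
class KeyboardLayout:
    """Eight ordered symbol groups covering the full symbol set."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 8:
            raise KeyboardError("layout requires exactly 8 groups")
        flat = [s for g in self.groups for s in g]
        if len(set(flat)) != len(flat):
            raise KeyboardError("each symbol must appear in exactly one group")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s for g in self.groups for s in g)

    def group_of(self, symbol: str) -> int:
        for k, g in enumerate(self.groups):
            if symbol in g:
                return k
        raise KeyboardError(f"symbol {symbol!r} not in layout")

    def resolve(self, symbol: str) -> tuple[int, int]:
        """(group index, position within group) of ``symbol``."""
        g = self.group_of(symbol)
        return g, self.groups[g].index(symbol)


def default_layout() -> KeyboardLayout:
    """26 letters + '?' + space in alphabetical fours, plus the control pair."""
    return KeyboardLayout(groups=(
        ("a", "b", "c", "d"),
        ("e", "f", "g", "h"),
        ("i", "j", "k", "l"),
        ("m", "n", "o", "p"),
        ("q", "r", "s", "t"),
        ("u", "v", "w", "x"),
        ("y", "z", "?", SPACE),
        (BACKSPACE, ACCEPT),
    ))


@dataclass(frozen=True)
class SymbolSelection:
    """Stats of one two-stage symbol entry."""

    symbol: str
    n_eliminations: int
    n_cycles: int
    elapsed_time: float
    stage_outcomes: tuple[SelectionOutcome, SelectionOutcome]


# selector signature: (items, target_item) -> SelectionOutcome
Selector = Callable[[Sequence[str], str], SelectionOutcome]

_GROUP_TOKEN = "group:{}"


def select_symbol(
    layout: KeyboardLayout,
    target: str,
    selector: Selector,
) -> SymbolSelection:
    """Enter one symbol: group selection, then within-group selection.

    ``selector`` runs one complete decoder selection over a set of items
    with a given attended target.  If the group stage resolves to a
    group that does not contain the intended symbol, the within-group
    intent falls back to that group's first symbol (the writer must
    select something, and corrects with backspace afterwards).
    """
    g_target = layout.group_of(target)
    group_items = [_GROUP_TOKEN.format(k) for k in range(len(layout.groups))]
    stage1 = selector(group_items, _GROUP_TOKEN.format(g_target))
    g_chosen = int(stage1.selected_item.split(":")[1])
    members = layout.groups[g_chosen]
    stage2_target = target if target in members else members[0]
    stage2 = selector(members, stage2_target)
    return SymbolSelection(
        symbol=stage2.selected_item,
        n_eliminations=stage1.n_eliminations + stage2.n_eliminations,
        n_cycles=stage1.n_cycles + stage2.n_cycles,
        elapsed_time=stage1.elapsed_time + stage2.elapsed_time,
        stage_outcomes=(stage1, stage2),
    )


@dataclass(frozen=True)
class TextSession:
    """Text-entry state: buffer, full symbol log, per-symbol durations."""

    buffer: str = ""
    entered: tuple[str, ...] = ()
    durations: tuple[float, ...] = ()
    accepted: bool = False


def apply_symbol(
    session: TextSession,
    symbol: str,
    duration: float | None = None,
) -> TextSession:
    """Apply one selected symbol to the session.

    Characters and space append to the buffer; backspace removes the
    last character (a no-op on an empty buffer); accept closes the
    session.  Input after accept is an error.
    """
    if session.accepted:
        raise KeyboardError("session already accepted; no further input")
    if symbol == BACKSPACE:
        buffer = session.buffer[:-1]
        accepted = False
    elif symbol == ACCEPT:
        buffer = session.buffer
        accepted = True
    elif len(symbol) == 1:
        buffer = session.buffer + symbol
        accepted = False
    else:
        raise KeyboardError(f"unknown symbol {symbol!r}")
    durations = session.durations
    if duration is not None:
        durations = durations + (float(duration),)
    return TextSession(buffer=buffer, entered=session.entered + (symbol,),
                       durations=durations, accepted=accepted)


def session_stats(
    session: TextSession,
    durations: Sequence[float] | None = None,
    n_options: int = 30,
    itr_accuracy: float = 1.0,
) -> dict[str, float]:
    """Symbol/character accounting and the functional ITR of a session.

    ``n_symbols_entered`` counts every selection including backspace and
    accept; ``n_useful_characters`` is the length of the accepted text.
    The functional ITR treats each useful character as one selection
    among ``n_options`` alternatives taking the mean seconds per useful
    character; the exact definition is configurable and is not claimed
    to reproduce any externally reported value.
    """
    if not session.accepted:
        raise KeyboardError("session_stats requires an accepted session")
    durs = tuple(durations) if durations is not None else session.durations
    if durs and len(durs) != len(session.entered):
        raise KeyboardError("durations do not match the entered-symbol log")
    n_entered = len(session.entered)
    n_useful = len(session.buffer)
    total_time = float(sum(durs)) if durs else math.nan
    s_per_symbol = total_time / n_entered if n_entered and durs else math.nan
    s_per_useful = total_time / n_useful if n_useful and durs else math.nan
    functional_itr = (
        wolpaw_itr(n_options, itr_accuracy, s_per_useful)
        if n_useful and durs else math.nan
    )
    return {
        "n_symbols_entered": n_entered,
        "n_useful_characters": n_useful,
        "s_per_symbol": s_per_symbol,
        "s_per_useful_char": s_per_useful,
        "functional_itr": functional_itr,
    }


def write_text(
    layout: KeyboardLayout,
    target_text: str,
    selector: Selector,
    max_symbols: int = 400,
) -> TextSession:
    """Write ``target_text`` with a simple error-correcting intent policy.

    The intended symbol is the next needed character while the buffer is
    a prefix of the target, backspace when it is not, and accept once
    the buffer matches.  Selection errors made by the decoder therefore
    trigger corrective backspaces, exactly as a participant would.
    """
    for ch in target_text:
        if ch not in layout.symbols:
            raise KeyboardError(f"character {ch!r} not on the keyboard")
    session = TextSession()
    while not session.accepted:
        if len(session.entered) >= max_symbols:
            raise KeyboardError("max_symbols exceeded before text was accepted")
        if session.buffer == target_text:
            intent = ACCEPT
        elif target_text.startswith(session.buffer):
            intent = target_text[len(session.buffer)]
        else:
            intent = BACKSPACE
        sel = select_symbol(layout, intent, selector)
        session = apply_symbol(session, sel.symbol, duration=sel.elapsed_time)
    return session
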