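"""Free writing on the hierarchical keyboard with a simulated participant.

Each symbol costs a one-of-eight group selection plus a one-of-four
(or, for backspace/accept, one-of-two) selection.  Decoder errors
produce wrong characters, which the writer corrects with backspace, so
the entered-symbol count can exceed the useful text length.  An
erroneous selection can even land on 'accept', ending the session early
with a typo -- the same failure mode real sessions exhibit.
"""

import numpy as np

from pupilhci import ClosedLoopSimulator, DecoderConfig, ParticipantProfile
from pupilhci.keyboard import default_layout, session_stats, write_text

sim = ClosedLoopSimulator(ParticipantProfile(), DecoderConfig(),
                          sample_rate=250.0, rng=np.random.default_rng(12))
session = write_text(default_layout(), "le chat dort", sim.select,
                     max_symbols=120)
stats = session_stats(session)

print(f"accepted text        : {session.buffer!r}")
print(f"symbols entered      : {stats['n_symbols_entered']} "
      f"(incl. backspace/accept)")
print(f"useful characters    : {stats['n_useful_characters']}")
print(f"time per symbol      : {stats['s_per_symbol']:.1f} s")
print(f"functional ITR       : {stats['functional_itr']:.2f} bits/min")
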