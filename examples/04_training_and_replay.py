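"""Training criteria and offline replay.

First, simulated block accuracies are scored against the training
rules (success = 100% on a block >= 6, or >= 80% on block 12; one
retry at the conservative threshold T = 1.5).  Then a recorded session
is replayed offline from its exported trace and event log, reproducing
the live outcomes exactly.
"""

import numpy as np

from pupilhci import DecoderConfig, ParticipantProfile, training_outcome
from pupilhci.io import replay
from pupilhci.pupilsim import simulate_session

# --- training criteria on simulated blocks ------------------------------
profile = ParticipantProfile()
block_accuracies = []
for block in range(1, 13):
    records = simulate_session(profile, 2, 16, DecoderConfig(),
                               seed=100 + block, block_index=block)
    block_accuracies.append(float(np.mean([r.correct for r in records])))
    result = training_outcome(block_accuracies)
    if result.status == "success":
        break

print("block accuracies:",
      " ".join(f"{a:.0%}" for a in block_accuracies))
print(f"training outcome: {result.status} at block {result.stop_block} "
      f"(threshold {result.threshold})")

# --- replay fidelity -----------------------------------------------------
records, recording = simulate_session(profile, 4, 4, DecoderConfig(),
                                      seed=55, record=True)
replayed = replay(recording.trace, recording.events, DecoderConfig())
identical = replayed == recording.outcomes
print(f"replayed {len(replayed)} selections from the exported trace; "
      f"bit-identical to live: {identical}")
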