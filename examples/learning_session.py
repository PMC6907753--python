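"""One dyad learning to collaborate through fictitious play.

Simulates a full experimental session (13 epochs x 12 trials: baseline,
training with catch trials, after-effect) for a haptic-only (H) and a
partner-visible (PV) dyad.  Every trial, each simulated player plans a
best response to the partner-command trajectory extracted by their own
observer on previous connected trials.  Prints the epoch-by-epoch mean
interaction force and the role-specialization index.
"""

import numpy as np

import dyadgame as dg
from dyadgame.indicators import aggregate_epochs, session_indicators
from dyadgame.synthetic import make_protocol

plant = dg.build_plant(dg.DyadParams())
g = plant.geometry

for group in ("H", "PV"):
    session = dg.run_protocol(make_protocol(group, seed=3), plant, seed=3)
    table = session_indicators(session.records, g.vp1, g.vp2)
    epochs = aggregate_epochs(table, session.spec)
    training = epochs[epochs.phase == "training"]
    print(f"group {group}: mean IF per training epoch (N)")
    print("  " + "  ".join(f"{v:.3f}" for v in training.IF))
    print(f"  |dLI2| first epoch {abs(training.dLI2.values[0]):.3f} W -> "
          f"last epoch {abs(training.dLI2.values[-1]):.3f} W")

# The interaction force decreases over training in both groups as the
# partner estimates stabilize.  The haptic-only dyad keeps a larger
# terminal role index (|dLI2|) than the partner-visible dyad: with less
# reliable information the learned collaboration stays closer to the
# alternating leader-follower pattern of no-partner play.
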