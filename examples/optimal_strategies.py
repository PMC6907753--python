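"""Optimal (Nash) vs 'no-partner' dyad strategies on the via-point task.

Solves the two-player differential game for the default task — two
point masses coupled by a 150 N/m spring, reaching 10 cm through
different via-points — and contrasts the feedback-Nash solution with
the no-partner solution in which each player treats the other's action
as noise.  Prints the collaboration indicators of both noiseless
rollouts.
"""

import numpy as np

import dyadgame as dg
from dyadgame.indicators import trial_indicators
from dyadgame.learning import merge_policies

plant = dg.build_plant(dg.DyadParams())
cost1, cost2 = dg.build_cost(1, plant), dg.build_cost(2, plant)

nash = dg.solve_nash(plant, cost1, cost2)
no_partner = merge_policies(dg.solve_no_partner(plant, cost1),
                            dg.solve_no_partner(plant, cost2))

g = plant.geometry
for name, policy in [("Nash", nash), ("no-partner", no_partner)]:
    rec = dg.simulate_closed_loop(plant, policy)
    row = trial_indicators(rec, g.vp1, g.vp2)
    print(f"{name:>11}:  IF = {row.IF:.3f} N   peak|F| = "
          f"{np.abs(rec.F1).max():.3f} N")
    print(f"             MD12 = {row.MD12 * 100:.2f} cm  MD21 = "
          f"{row.MD21 * 100:.2f} cm   (distance from the partner's via-point)")
    print(f"             dLI1 = {row.dLI1:+.4f} W  dLI2 = {row.dLI2:+.4f} W"
          "   (role specialization at VP1 / VP2)")

rep = dg.verify_nash(plant, cost1, cost2, nash, n_perturb=100, seed=1)
print(f"\nNash check: best unilateral cost improvement over 100 random "
      f"deviations per player = {max(rep['max_improvement'].values()):.2e} "
      "(<= 1e-6 certifies the equilibrium)")

# Reading the numbers: under the Nash strategies the dyad negotiates one
# path through both via-points, so the interaction force and both MD
# values are an order of magnitude smaller.  No-partner players each
# track only their own via-point: the spring stretches (13x the mean
# force), each player stays up to ~2 cm from the partner's via-point,
# and the positive dLI values mark the alternating leader/follower
# roles — each player leads at their own via-point and is pulled through
# the partner's.
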