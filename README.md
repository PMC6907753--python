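# dyadgame

Computational models and analysis tools for **physically coupled joint
action**: two people (a dyad), mechanically connected through a virtual
spring, reach from a shared start to a shared target but through
*different* via-points that only they can see, while keeping the
interaction force low.  Collaboration is not given — it has to be
negotiated through the coupling.  `dyadgame` is aimed at researchers in
sensorimotor control and human-robot interaction who want to simulate,
predict and analyze such interactions end-to-end without external data.

## What it implements

**Dyad plant.** Two planar point masses with muscle-like activation
dynamics (eight state variables per player), coupled by a linear spring
`F₁ = −k(x₁ − x₂)` with `k = 150` N/m, discretized at 100 Hz:

    x(t+1) = A·x(t) + B₁·[u₁(t) + η₁(t)] + B₂·[u₂(t) + η₂(t)]

with additive Gaussian motor noise η and per-player linear-Gaussian
sensory channels `yᵢ = Hᵢ·x + vᵢ` that encode the three experimental
groups: haptic only (H), visuo-haptic (VH: the force vector is also
displayed), partner-visible (PV: the partner's cursor is shown).

**Differential game.** Each player has a quadratic cost
`Jᵢ = Σₜ x'Qᵢ(t)x + uᵢ'Rᵢuᵢ` encoding their own via-point, the shared
target, the effort, and the inter-player distance.  The package computes

* the **feedback Nash equilibrium** (coupled Riccati recursion; the
  optimal non-cooperative collaboration, verified against the Nash
  inequalities by random unilateral deviations),
* the **no-partner** solution (each player treats the other's action as
  noise — an independent LQG controller; the model of non-collaboration),
* the **open-loop Nash equilibrium** (mutually best-responding input
  sequences; the fixed point of fictitious play).

**Partner estimation.** Each player runs a Kalman observer on a plant
augmented with the partner's command, modelled as a slowly varying
latent input `u₋ᵢ(t+1) = A_u·u₋ᵢ(t) + ε(t)`.  The filter fuses the
efference copy of one's own commands with the group's sensory channels;
an RTS (forward-backward) pass extracts a lag-free partner-command
trajectory from a completed trial.

**Learning.** A fictitious-play loop over the full experimental
protocol (1 baseline + 10 training + 2 after-effect epochs of 12 trials,
2 random catch trials per training epoch): each trial, every player
best-responds to the partner commands estimated from previous connected
trials — feedback gains plus a feedforward term carrying the predicted
partner contribution.

**Indicators.** The behavioral pipeline applied identically to simulated
and recorded trials: Savitzky-Golay smoothing (order 4, 370 ms window),
2 cm/s movement segmentation, the 0–100 logistic score, trial-mean
interaction force (IF), minimum via-point distances (MD_ij), interaction
power `Pᵢ = Fᵢ·vᵢ` (negative = leading, positive = being pulled), and
leadership indices LI_ij / ΔLI over the 300 ms before each via-point
crossing, with 12-trial epoch aggregation.

## Worked example

```bash
python examples/optimal_strategies.py
```

```
       Nash:  IF = 0.045 N   peak|F| = 0.149 N
             MD12 = 0.06 cm  MD21 = 0.09 cm   (distance from the partner's via-point)
             dLI1 = +0.0043 W  dLI2 = +0.0273 W   (role specialization at VP1 / VP2)
 no-partner:  IF = 0.600 N   peak|F| = 1.566 N
             MD12 = 0.67 cm  MD21 = 1.72 cm   (distance from the partner's via-point)
             dLI1 = +0.0071 W  dLI2 = +0.0107 W   (role specialization at VP1 / VP2)

Nash check: best unilateral cost improvement over 100 random deviations per player = 0.00e+00 (<= 1e-6 certifies the equilibrium)
```

Under the Nash strategies the dyad shares one path through both
via-points: the mean interaction force is 13× smaller and each player
passes within a millimeter of the *partner's* via-point.  No-partner
players only track their own goal, so the spring stretches and the
positive ΔLI values mark alternating leader/follower roles.  Other
examples: `partner_estimation.py` (the H→VH→PV information gradient in
partner-command tracking), `learning_session.py` (interaction force
falling over training epochs, with the haptic-only group retaining
stronger roles than the partner-visible group), `analyze_trials.py`
(the indicator pipeline on raw CSV trials).

A thin CLI mirrors the library: `dyadgame config --show-defaults`,
`dyadgame verify-nash`, `dyadgame simulate`, `dyadgame analyze`,
`dyadgame dataset`.

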