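# Methods

## The model

Two players jointly control one mechanical system: two planar point
masses connected by a linear spring of stiffness `k` (default 150 N/m;
`k = 0` disconnects them).  Each player drives their own mass through a
muscle-like activation cascade — two first-order low-pass filters per
axis — so one player contributes 8 state variables (position, velocity,
and 4 activation states).  The target and the two via-points are
appended to the state vector (6 more dimensions, constant during a
trial) so that every task error is linear in the 22-dimensional state
and all costs stay quadratic.  The continuous dynamics per player are

    ṗ = v
    m·v̇ = f − b·v − k·(p − p_other)
    τ₁·ḟ = g − f
    τ₂·ġ = u − g

discretized by exact zero-order hold at dt = 10 ms (forward Euler is
available for comparison).  Motor noise is additive Gaussian on the
commands; sensory channels are linear with additive Gaussian noise.

The viscous term `b` (default 12 N·s/m) represents the intrinsic
impedance of the hand plus the haptic handle.  It matters beyond
realism: policies planned on the *coupled* plant contain anticipatory
feedback on the partner's position, and on a silently disconnected
plant (catch trials) that feedback is no longer balanced by the spring.
Without damping the mismatched loop is exponentially unstable
(spectral radius ≈ 1.07 per step — a factor 10⁵ over one trial); with
`b = 12` the transient stays bounded and shows up as an after-effect,
which is the behavior catch trials are meant to probe.

## Tasks and controllers

Each player's finite-horizon quadratic cost contains: the distance to
their *own* via-point at a single designated step (defaults: 35% of the
horizon for player 1, 65% for player 2, matching the via-point layout),
the distance to the target plus a stopping term at the final step, a
running penalty on the inter-player distance ‖p₁ − p₂‖² (the spring
force equals k(p₁ − p₂), so this is the force requirement up to k²),
and a control-effort term.

Three solution concepts are implemented:

* **Feedback Nash** (`solve_nash`): the standard backward coupled
  Riccati recursion for two-player LQ games; at each stage the stacked
  best-response system is solved exactly and a singular stage raises an
  error naming the step.  `verify_nash` certifies a solution by random
  unilateral gain perturbations: each perturbation touches one random
  time step with a log-uniform amplitude, because a dense perturbation
  of the whole gain sequence is dominated by its quadratic cost penalty
  in ~9000 dimensions and would never detect a non-equilibrium point.
* **No-partner** (`solve_no_partner`): the partner's command is treated
  as zero-mean noise; by certainty equivalence the gains are the plain
  single-player LQR gains on the same plant (the assumed noise
  covariance matters only to observers).
* **Open-loop Nash** (`solve_open_loop_nash`): simultaneous
  best-response iteration over committed input *sequences* to a fixed
  point.  This is deliberately distinct from the feedback Nash: a
  player best-responding to a fixed sequence cannot rely on the partner
  reacting to deviations, and the two equilibria produce measurably
  different trajectories on this task.  Fictitious play over estimated
  input trajectories can only be absorbed by the open-loop equilibrium,
  and the absorbing-state test uses it accordingly.

Default cost weights (w_vp = w_target = 10⁴ m⁻², w_stop = 10² s²/m²,
w_force = 300 m⁻², w_effort = 10⁻³ N⁻²) were calibrated once, jointly:
noiseless Nash rollouts pass within 5 mm of both via-points and stop on
the target; the closed loop tolerates observer noise without
divergence; and the fictitious-play fixed point has a lower interaction
force than no-partner play, so that learning has somewhere to go.  With
a much weaker w_force the fixed point sits *above* no-partner play —
each player uses the partner prediction to hold their own course rather
than to compromise.

## Observer and partner model

Each player filters an augmented 24-dimensional state `[x; u_partner]`
where the partner's command follows a decaying random walk
`u(t+1) = A_u·u(t) + ε` with 0 < A_u < 1.  Defaults A_u = 0.99 and
σ_ε = 0.5 N per step: per-sample kinematic measurements carry little
information about a ~1 N force, so the prior must be smooth enough to
integrate over ~100 samples, yet not so stiff that a sustained input is
shrunk toward the zero-mean prior.  Kalman gains are data independent
and precomputed once per sensory configuration (Joseph-form updates,
symmetrized covariances; a degenerate noise-free channel falls back to
a pseudo-inverse gain, which reproduces the exact-correction limit).

Two deliberate departures from the textbook filter:

* **Process-noise floor** (std 10⁻³ per step on the 16 dynamic states):
  the nominal process noise `B Ση B'` is rank-2, which makes the filter
  absolutely certain of the forward model everywhere else; any dynamics
  mismatch (catch trials) then destabilizes the estimate-driven loop.
  The floor encodes model uncertainty; the static goal block is exempt.
* **RTS smoothing between trials** (`smoothed_partner_inputs`): the
  causal filter lags the partner's command by ~0.2 s.  Within a trial
  that is unavoidable, but the between-trial best response may use the
  whole completed trial, so the partner-command trajectory handed to
  planning comes from the forward-backward pass.  Best-responding to
  the lagged causal estimate instead produces systematically mistimed
  feedforward and raises, rather than lowers, the interaction force.

Estimation behaves differently for constant and time-varying inputs,
and tests treat them separately: a *constant* input is recovered nearly
unbiasedly (the low-noise recovery check), but steady-state RMSE under
a constant input *decreases* with worse sensors (smaller gains pass
less noise), so the information ordering H > VH > PV is a statement
about *tracking* time-varying partner commands and is tested with a
smooth sinusoidal input.

Default sensory noise (std per channel): own position 5 mm, own
velocity 10 mm/s, via-point and target 1 mm, interaction force 1.0 N
haptically (H, PV) and 0.3 N when displayed (VH), partner cursor 1 mm
(PV only).  The VH force display at 0.3 N is equivalent to 2 mm on the
position difference (σ/k), so the PV cursor channel must be sharper
than that for PV to be the best-informed group, which is the design
intent of the three conditions.

## Fictitious play

Trial t's policies are best responses to each player's own estimate of
the partner-command trajectory, implemented as an affine LQ problem
whose drift `B₋ᵢ·û₋ᵢ(t)` yields the usual feedback gains plus a
feedforward term; the Riccati pass is estimate independent and cached.
Estimates update only from connected trials.  The belief is an
exponential average over past trials' smoothed estimates (weight 0.85,
i.e. a ~7-trial memory): fictitious play in its canonical form
best-responds to the empirical average of past play, and the averaging
is what turns single-trial estimation noise into a gradually improving
belief — with the most recent trial only, the learning curve collapses
into the first epoch and then fluctuates.  Baseline and after-effect
trials use the solo policy (disconnected plant, no inter-player
distance term — the task is scored individually there); catch trials
run the training-trial controllers and observers on the disconnected
plant, unbeknownst to the players.

## Indicators

All quantities are planar (X, Y).  Positions and forces are smoothed by
a 4th-order Savitzky-Golay filter with a 370 ms (37-sample) window;
velocities and accelerations come from the same local fits.  A movement
is the span from the first to the last sample at or above 2 cm/s; the
dyad-level window is the union of the two players' windows, so IF, the
mean inter-player distance d₁₂, and both players' indicators share one
window (whether d₁₂ is averaged over the movement or the whole
recording is not otherwise determined; the movement window is used).

The score is `100 / (1 + exp(h·(d − d₀)))` with `d = d_VP + c·d₁₂`,
c = 0.5 when connected and 0 otherwise.  The logistic cannot literally
reach 100 or 0, so h and d₀ are set by symmetry: d₀ = 12.5 mm (midpoint
of the stated saturation band) and h = 800 m⁻¹, which makes the
*displayed*, integer-rounded score 100 at d = 5 mm and 0 at d = 20 mm,
and exactly 50 at d₀.

Via-point "crossing" is operationalized as the sample at which the
via-point's homologous player passes closest to it; both players' LI at
that via-point share this window (mean power over the preceding 300 ms,
truncated if the crossing is early).  ΔLI₁ = LI₂₁ − LI₁₁ and
ΔLI₂ = LI₁₂ − LI₂₂.  Epoch aggregation uses 12-trial means with catch
trials excluded from connected-phase means; the early/middle/late
labels map to the 1st, 6th and 10th training epochs (a 10-epoch
training phase has no 11th epoch, so "late" is the last one).

## Synthetic data

`generate_group_dataset` runs the full learning model per dyad
(distinct child seeds) and writes raw trial CSVs plus one
indicator matrix per indicator with one row per dyad and one column per
trial (5 × 156 at defaults).  `make_fixture_trial` builds model-free
minimum-jerk two-player paths through start → VP1 → VP2 → target with a
controllable lead/lag τ between the players (positive τ: player 2
leads), forces from the spring law on the generated positions.  These
fixtures have indicator values known by construction — MD to the own
via-point is 0, τ = 0 gives zero force and zero ΔLI, and |ΔLI| grows
monotonically with τ — which gives the analysis pipeline a controlled
dose-response test that does not depend on the control model.

What the generator does *not* emulate: signal-dependent (multiplicative)
motor noise, movement-onset asynchrony between the players, trial
durations outside the instructed band, nonplanar (Z) motion, and any
within-trial re-planning.  Passing tests therefore certify the
machinery and its qualitative predictions (force reduction with
learning, information-dependent role retention), not quantitative
agreement with human data.

## Numerical choices

Zero-order-hold discretization is exact for the linear plant; the
coupled and single-player Riccati recursions symmetrize their value
matrices each step; observer covariances use Joseph updates and are
symmetrized; the open-loop Nash iteration declares convergence when no
input entry moves by more than 10⁻¹⁰ N (about 300 Jacobi sweeps at the
default coupling).  Closed-loop simulation aborts with the step index
if the state norm exceeds 10⁶.  Nash verification uses noiseless
rollouts (no Monte-Carlo variance in the inequality check) and a
relative tolerance of 10⁻⁶.  Default problem sizes — 200-step trials,
156-trial sessions, 5 dyads per generated group, 5–10 seeds in
Monte-Carlo tests — keep a full test run in the minutes range while
leaving the group-level orderings strict per seed.

## Known limitations

* The activation time constants (40 ms each), masses (1 kg), damping
  and all noise magnitudes are declared package defaults, not
  measurements; they are config-overridable.
* The fictitious-play loop re-plans between trials only; each trial's
  policy is fixed for its duration.
* Players start each trial simultaneously from the same state.
* Group-level inferential statistics (ANOVA and post-hoc tests on human
  data) are out of scope; the package computes the indicators those
  analyses would consume.
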