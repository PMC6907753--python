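"""Fictitious-play learning over the experimental protocol.

Each trial, every player plans a best response to the partner-command
trajectory that their own observer extracted on the previous connected
trial: the plant each player "sees" is the dyad dynamics plus a known
time-varying drift ``B_other * u_hat(t)``, which turns the LQ problem
into an affine one whose solution has the usual feedback gains plus a
feedforward term carrying the predicted partner contribution.  On the
first trial the estimate is zero, so play starts from the no-partner
policy.  Disconnected trials (baseline, catch, after-effect) never
update the partner estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .control import AffineLQR, PolicySet, simulate_closed_loop
from .observer import (
    DEFAULT_A_U,
    DEFAULT_SIGMA_EPS,
    KalmanObserver,
    initial_observer_state,
    kalman_gain_schedule,
    smoother_gain_schedule,
)
from .plant import PlantModel, build_sensory_model
from .records import TrialRecord
from .tasks import CostSpec, build_cost

TRIALS_PER_EPOCH = 12
N_TRAINING_EPOCHS = 10
CATCH_PER_EPOCH = 2


@dataclass
class PartnerEstimate:
    """One player's belief about the partner's command trajectory."""

    player_id: int                 # the owner of the belief
    u_hat_seq: np.ndarray          # (T-1, 2): u_hat_seq[t-1] = u_partner(t)
    source_trial: int = -1         # trial index it was extracted from (-1: prior)

    def __post_init__(self) -> None:
        self.u_hat_seq = np.asarray(self.u_hat_seq, dtype=float)
        if self.u_hat_seq.ndim != 2 or self.u_hat_seq.shape[1] != 2:
            raise ValueError("u_hat_seq must have shape (T-1, 2)")
        if not np.all(np.isfinite(self.u_hat_seq)):
            raise ValueError("partner estimate must be finite")


def zero_estimate(player_id: int, T: int) -> PartnerEstimate:
    return PartnerEstimate(player_id=player_id, u_hat_seq=np.zeros((T - 1, 2)))


@dataclass
class EpochSpec:
    phase: str          # baseline | training | after_effect
    n_trials: int
    connected: bool
    n_catch: int = 0


@dataclass
class ProtocolSpec:
    """Trial schedule: 1 baseline + 10 training + 2 after-effect epochs.

    Catch trials (silently disconnected) occur only in training, drawn
    uniformly without replacement within each epoch from ``seed``.
    """

    epochs: list[EpochSpec] = field(default_factory=lambda: (
        [EpochSpec("baseline", TRIALS_PER_EPOCH, False)]
        + [EpochSpec("training", TRIALS_PER_EPOCH, True, CATCH_PER_EPOCH)
           for _ in range(N_TRAINING_EPOCHS)]
        + [EpochSpec("after_effect", TRIALS_PER_EPOCH, False)
           for _ in range(2)]))
    group: str = "H"
    seed: int = 0

    def __post_init__(self) -> None:
        for ep in self.epochs:
            if ep.n_catch and ep.phase != "training":
                raise ValueError("catch trials occur only in training epochs")

    @property
    def n_trials(self) -> int:
        return sum(ep.n_trials for ep in self.epochs)

    def trial_table(self) -> list[dict]:
        """Flat per-trial schedule with seeded catch-trial placement."""
        rng = np.random.default_rng(self.seed)
        table = []
        idx = 0
        for e, ep in enumerate(self.epochs):
            catch_local = set()
            if ep.n_catch:
                catch_local = set(rng.choice(ep.n_trials, size=ep.n_catch,
                                             replace=False).tolist())
            for j in range(ep.n_trials):
                catch = j in catch_local
                table.append({
                    "trial": idx, "epoch": e, "phase": ep.phase,
                    "connected": ep.connected and not catch,
                    "catch": catch,
                })
                idx += 1
        return table


def best_response_policy(plant: PlantModel, cost_i: CostSpec,
                         estimate: PartnerEstimate,
                         lqr: AffineLQR | None = None) -> PolicySet:
    """Optimal policy of one player against a predicted partner trajectory.

    The predicted commands enter the player's planning model as the
    known drift ``c(t) = B_other u_hat(t)``; the resulting policy has
    feedback gains identical to the no-partner LQR plus a feedforward
    term that pre-compensates the partner's predicted pull.
    """
    T = cost_i.T
    if estimate.u_hat_seq.shape[0] != T - 1:
        raise ValueError("estimate length must match the horizon")
    player = cost_i.player_id
    B_own = plant.B1 if player == 1 else plant.B2
    B_other = plant.B2 if player == 1 else plant.B1
    if lqr is None:
        lqr = AffineLQR(plant.A, B_own, cost_i.Q_seq, cost_i.R, T)
    c_seq = np.zeros((T, plant.A.shape[0]))
    c_seq[1:] = estimate.u_hat_seq @ B_other.T
    f_seq = lqr.feedforward(c_seq)
    if player == 1:
        return PolicySet(L1_seq=lqr.L_seq, L2_seq=None, f1_seq=f_seq,
                         scenario="best_response",
                         meta={"source_trial": estimate.source_trial})
    return PolicySet(L1_seq=None, L2_seq=lqr.L_seq, f2_seq=f_seq,
                     scenario="best_response",
                     meta={"source_trial": estimate.source_trial})


def merge_policies(p1: PolicySet, p2: PolicySet, scenario: str = "pair") -> PolicySet:
    """Combine two one-sided policies into a dyad policy set."""
    return PolicySet(L1_seq=p1.L1_seq, L2_seq=p2.L2_seq,
                     f1_seq=p1.f1_seq, f2_seq=p2.f2_seq, scenario=scenario)


def run_trial(plant: PlantModel, policies: PolicySet,
              observers: tuple[KalmanObserver, KalmanObserver] | None,
              connected: bool, seed: int | None = None,
              with_noise: bool = True,
              record_kwargs: dict | None = None) -> TrialRecord:
    """One noisy closed-loop movement.

    ``connected=False`` zeroes the coupling spring in the *true*
    dynamics (baseline / catch / after-effect) while the controllers
    and observers keep whatever internal model they were built with.
    """
    true_plant = plant if connected else plant.disconnected()
    if observers is not None:
        for obs in observers:
            obs.reset()
    kwargs = dict(record_kwargs or {})
    kwargs.setdefault("connected", connected)
    return simulate_closed_loop(true_plant, policies, seed=seed,
                                with_noise=with_noise, observers=observers,
                                record_kwargs=kwargs)


@dataclass
class Session:
    """Ordered trial records of one simulated dyad plus belief history."""

    records: list[TrialRecord]
    estimates: list[tuple[PartnerEstimate, PartnerEstimate]]
    spec: ProtocolSpec
    seed: int
    meta: dict = field(default_factory=dict)


def run_protocol(spec: ProtocolSpec, plant: PlantModel,
                 costs: tuple[CostSpec, CostSpec] | None = None,
                 seed: int | None = None,
                 noise_profiles: dict | None = None,
                 A_u: float = DEFAULT_A_U,
                 sigma_eps: float = DEFAULT_SIGMA_EPS,
                 estimate_smoothing: float = 0.85,
                 with_noise: bool = True) -> Session:
    """Simulate a full experimental session of one dyad.

    Training trials use fictitious play: trial t's policies are best
    responses to each player's own observer-derived estimate of the
    partner's commands from the most recent connected trial (zero for
    the first one).  Baseline and after-effect trials use the solo
    (no-partner, disconnected-plant) policy with the inter-player
    distance weight dropped, since no coupling exists and the task is
    scored individually there.  ``estimate_smoothing`` in [0, 1) is the
    weight of the exponential average over earlier trials' estimates —
    the belief-averaging step of fictitious play (0 uses only the most
    recent connected trial).
    """
    if seed is None:
        seed = spec.seed
    group = spec.group
    T = plant.horizon_T
    if costs is None:
        costs = (build_cost(1, plant), build_cost(2, plant))
    cost1, cost2 = costs

    # solo problem: disconnected plant, no inter-player distance penalty
    plant_solo = plant.disconnected()
    solo_w = {"w_force": 0.0}
    solo_costs = (build_cost(1, plant_solo, weights={**cost1.weights, **solo_w}),
                  build_cost(2, plant_solo, weights={**cost2.weights, **solo_w}))
    solo_lqr = {i: AffineLQR(plant_solo.A,
                             plant_solo.B1 if i == 1 else plant_solo.B2,
                             solo_costs[i - 1].Q_seq, solo_costs[i - 1].R, T)
                for i in (1, 2)}
    train_lqr = {i: AffineLQR(plant.A, plant.B1 if i == 1 else plant.B2,
                              costs[i - 1].Q_seq, costs[i - 1].R, T)
                 for i in (1, 2)}

    def make_observers(model_plant: PlantModel) -> tuple[KalmanObserver, KalmanObserver]:
        obs = []
        for i in (1, 2):
            sensory = build_sensory_model(group, model_plant, player_id=i,
                                          noise_profile=noise_profiles)
            ob = KalmanObserver(model_plant, sensory, A_u=A_u,
                                Sigma_eps=sigma_eps**2 * np.eye(2))
            K_seq, P_post, P_prior = kalman_gain_schedule(
                ob.aug, sensory, initial_observer_state(model_plant).P, T,
                return_priors=True)
            ob.K_seq = K_seq
            ob.G_seq = smoother_gain_schedule(ob.aug, P_post, P_prior)
            ob.record_history = True
            obs.append(ob)
        return obs[0], obs[1]

    observers_train = make_observers(plant)
    observers_solo = make_observers(plant_solo)

    estimates = {1: zero_estimate(1, T), 2: zero_estimate(2, T)}
    trial_seeds = np.random.SeedSequence(seed).generate_state(spec.n_trials) % (2**31)

    records: list[TrialRecord] = []
    est_history: list[tuple[PartnerEstimate, PartnerEstimate]] = []
    solo_policy = merge_policies(
        PolicySet(L1_seq=solo_lqr[1].L_seq, L2_seq=None, scenario="no_partner"),
        PolicySet(L1_seq=None, L2_seq=solo_lqr[2].L_seq, scenario="no_partner"),
        scenario="no_partner")

    for row in spec.trial_table():
        training = row["phase"] == "training"
        rec_kwargs = {"trial_index": row["trial"], "phase": row["phase"],
                      "catch": row["catch"]}
        if training:
            pol = merge_policies(
                best_response_policy(plant, cost1, estimates[1], lqr=train_lqr[1]),
                best_response_policy(plant, cost2, estimates[2], lqr=train_lqr[2]),
                scenario="fictitious_play")
            observers = observers_train
        else:
            pol = solo_policy
            observers = observers_solo
        rec = run_trial(plant, pol, observers, connected=row["connected"],
                        seed=int(trial_seeds[row["trial"]]),
                        with_noise=with_noise, record_kwargs=rec_kwargs)
        records.append(rec)
        if row["connected"]:
            for i, obs_i in ((1, observers[0]), (2, observers[1])):
                # lag-free partner-command series from the backward pass;
                # smoothed[j] estimates u_partner(t=j), wanted for t=1..T-1
                smoothed = obs_i.smoothed_partner_inputs()
                new = np.vstack([smoothed[1:], smoothed[-1:]])
                if estimate_smoothing > 0 and estimates[i].source_trial >= 0:
                    new = (estimate_smoothing * estimates[i].u_hat_seq
                           + (1 - estimate_smoothing) * new)
                estimates[i] = PartnerEstimate(player_id=i, u_hat_seq=new,
                                               source_trial=row["trial"])
        est_history.append((estimates[1], estimates[2]))

    return Session(records=records, estimates=est_history, spec=spec, seed=seed,
                   meta={"group": group, "A_u": A_u, "sigma_eps": sigma_eps})
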