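"""Feedback-Nash and no-partner controllers, and closed-loop simulation.

The two-player finite-horizon linear-quadratic game is solved by the
standard backward coupled Riccati recursion: at each stage both players'
best-response conditions form one linear system in the stacked gains,
which is solved exactly.  The "no-partner" scenario treats the other
player's command as zero-mean noise, which by certainty equivalence
reduces to an ordinary single-player LQR on the same plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plant import STATE_DIM, PlantModel, interaction_force, step_dynamics
from .records import TrialRecord
from .tasks import CostSpec, evaluate_cost

#: relative tolerance for "no unilateral improvement" in Nash verification
NASH_REL_TOL = 1e-6


@dataclass
class PolicySet:
    """Time-varying feedback gains (and optional feedforward) for both players.

    Policies act as ``u_i(t) = -L_i(t) x(t) + f_i(t)`` for t = 1..T-1;
    sequences are indexed ``L_seq[t-1]``.  Either player's entries may
    be ``None`` when the scenario fills only one side.
    """

    L1_seq: np.ndarray | None
    L2_seq: np.ndarray | None
    f1_seq: np.ndarray | None = None
    f2_seq: np.ndarray | None = None
    scenario: str = "nash"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for L in (self.L1_seq, self.L2_seq):
            if L is not None and not np.all(np.isfinite(L)):
                raise ValueError("policy gains must be finite")

    @property
    def horizon_T(self) -> int:
        L = self.L1_seq if self.L1_seq is not None else self.L2_seq
        return L.shape[0] + 1

    def control(self, player: int, t: int, x: np.ndarray) -> np.ndarray:
        """u_i(t) for t = 1..T-1."""
        L_seq = self.L1_seq if player == 1 else self.L2_seq
        f_seq = self.f1_seq if player == 1 else self.f2_seq
        if L_seq is None:
            return np.zeros(2)
        u = -L_seq[t - 1] @ x
        if f_seq is not None:
            u = u + f_seq[t - 1]
        return u


def solve_nash(plant: PlantModel, cost1: CostSpec, cost2: CostSpec) -> PolicySet:
    """Feedback Nash equilibrium of the finite-horizon two-player LQ game.

    Backward recursion on the pair of value matrices P1, P2: at stage t
    the stacked best-response system

        [R1 + B1'P1B1   B1'P1B2 ] [L1]   [B1'P1A]
        [B2'P2B1        R2+B2'P2B2] [L2] = [B2'P2A]

    is solved for both gains simultaneously, then each value matrix is
    propagated through the closed loop.
    """
    if cost1.T != cost2.T:
        raise ValueError("both costs must share the same horizon")
    T = cost1.T
    A, B1, B2 = plant.A, plant.B1, plant.B2
    P1 = cost1.Q_seq[T].copy()
    P2 = cost2.Q_seq[T].copy()
    L1_seq = np.zeros((T - 1, 2, STATE_DIM))
    L2_seq = np.zeros((T - 1, 2, STATE_DIM))
    for t in range(T - 1, 0, -1):
        S = np.zeros((4, 4))
        S[:2, :2] = cost1.R + B1.T @ P1 @ B1
        S[:2, 2:] = B1.T @ P1 @ B2
        S[2:, :2] = B2.T @ P2 @ B1
        S[2:, 2:] = cost2.R + B2.T @ P2 @ B2
        rhs = np.vstack([B1.T @ P1 @ A, B2.T @ P2 @ A])
        try:
            L = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular best-response system at step t={t}") from err
        L1, L2 = L[:2], L[2:]
        L1_seq[t - 1] = L1
        L2_seq[t - 1] = L2
        Acl = A - B1 @ L1 - B2 @ L2
        P1 = cost1.Q_seq[t] + L1.T @ cost1.R @ L1 + Acl.T @ P1 @ Acl
        P2 = cost2.Q_seq[t] + L2.T @ cost2.R @ L2 + Acl.T @ P2 @ Acl
        P1 = 0.5 * (P1 + P1.T)
        P2 = 0.5 * (P2 + P2.T)
    return PolicySet(L1_seq=L1_seq, L2_seq=L2_seq, scenario="nash",
                     meta={"P1_0": P1, "P2_0": P2})


class AffineLQR:
    """Finite-horizon LQR for ``x(t+1) = A x + B u + c(t)``.

    The optimal policy is ``u(t) = -L(t) x + f(t)``.  The backward
    Riccati pass (which fixes the feedback gains) is independent of the
    drift ``c``, so it runs once at construction; ``feedforward`` then
    computes ``f`` for any drift sequence with a cheap linear backward
    pass.  This is exactly the "dummy state" construction used by
    fictitious play — the drift carries the partner's predicted
    contribution and only ever shapes the feedforward term.
    """

    def __init__(self, A: np.ndarray, B: np.ndarray, Q_seq: np.ndarray,
                 R: np.ndarray, T: int):
        n, m = A.shape[0], B.shape[1]
        self.A, self.B, self.R, self.T = A, B, R, T
        self.L_seq = np.zeros((T - 1, m, n))
        # per-stage quantities needed by the feedforward pass, indexed t-1
        self._P_next = np.zeros((T - 1, n, n))
        self._G = np.zeros((T - 1, m, m))
        P = Q_seq[T].copy()
        for t in range(T - 1, 0, -1):
            G = R + B.T @ P @ B
            L = np.linalg.solve(G, B.T @ P @ A)
            self._P_next[t - 1] = P
            self._G[t - 1] = G
            self.L_seq[t - 1] = L
            Acl = A - B @ L
            P = Q_seq[t] + L.T @ R @ L + Acl.T @ P @ Acl
            P = 0.5 * (P + P.T)
        self.P0 = P

    def feedforward(self, c_seq: np.ndarray) -> np.ndarray:
        """Optimal feedforward for drift ``c_seq[t] = c(t)``, t = 1..T-1.

        ``c_seq`` has shape (T, n) with index 0 unused (drift acts on
        the transition from x(t) to x(t+1), t = 1..T-1).
        """
        A, B, R, T = self.A, self.B, self.R, self.T
        n, m = A.shape[0], B.shape[1]
        f_seq = np.zeros((T - 1, m))
        q = np.zeros(n)
        for t in range(T - 1, 0, -1):
            c = c_seq[t]
            P = self._P_next[t - 1]
            L = self.L_seq[t - 1]
            l = np.linalg.solve(self._G[t - 1], B.T @ (P @ c + q))
            Acl = A - B @ L
            q = L.T @ R @ l + Acl.T @ (P @ (c - B @ l) + q)
            f_seq[t - 1] = -l
        return f_seq


def solve_affine_lqr(A: np.ndarray, B: np.ndarray, Q_seq: np.ndarray,
                     R: np.ndarray, T: int,
                     c_seq: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One-shot convenience wrapper around :class:`AffineLQR`."""
    lqr = AffineLQR(A, B, Q_seq, R, T)
    if c_seq is None:
        f_seq = np.zeros((T - 1, B.shape[1]))
    else:
        f_seq = lqr.feedforward(np.asarray(c_seq, dtype=float))
    return lqr.L_seq, f_seq


def solve_no_partner(plant: PlantModel, cost_i: CostSpec,
                     partner_as_noise_cov: np.ndarray | None = None) -> PolicySet:
    """LQG policy of one player with the partner's command treated as noise.

    By certainty equivalence the optimal gains do not depend on the
    assumed partner-noise covariance (it matters only for the observer
    and for simulation), so this is the single-player LQR on the plant
    with only that player's input map.
    """
    B = plant.B1 if cost_i.player_id == 1 else plant.B2
    L_seq, _ = solve_affine_lqr(plant.A, B, cost_i.Q_seq, cost_i.R, cost_i.T)
    meta = {"partner_as_noise_cov": partner_as_noise_cov}
    if cost_i.player_id == 1:
        return PolicySet(L1_seq=L_seq, L2_seq=None, scenario="no_partner", meta=meta)
    return PolicySet(L1_seq=None, L2_seq=L_seq, scenario="no_partner", meta=meta)


def solve_open_loop_nash(plant: PlantModel, cost1: CostSpec, cost2: CostSpec,
                         x0: np.ndarray | None = None,
                         max_iter: int = 500, tol: float = 1e-10) -> dict:
    """Open-loop Nash equilibrium: mutually best-responding input sequences.

    Iterates simultaneous best responses to the partner's committed
    input *sequence* (each an exact affine-LQ solve) until the
    sequences stop changing.  This — not the feedback Nash of
    :func:`solve_nash` — is the fixed point of fictitious play over
    estimated input trajectories: a player best-responding to a fixed
    sequence cannot rely on the partner reacting to deviations, so the
    two equilibrium concepts give measurably different trajectories.
    """
    T = cost1.T
    if x0 is None:
        x0 = plant.initial_state()
    lqr1 = AffineLQR(plant.A, plant.B1, cost1.Q_seq, cost1.R, T)
    lqr2 = AffineLQR(plant.A, plant.B2, cost2.Q_seq, cost2.R, T)
    u1 = np.zeros((T - 1, 2))
    u2 = np.zeros((T - 1, 2))

    def best_response(lqr, B_own, u_other, B_other):
        c_seq = np.zeros((T, STATE_DIM))
        c_seq[1:] = u_other @ B_other.T
        f_seq = lqr.feedforward(c_seq)
        x = x0.copy()
        us = np.zeros((T - 1, 2))
        for t in range(1, T):
            u = -lqr.L_seq[t - 1] @ x + f_seq[t - 1]
            us[t - 1] = u
            x = plant.A @ x + B_own @ u + B_other @ u_other[t - 1]
        return us

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        u1_new = best_response(lqr1, plant.B1, u2, plant.B2)
        u2_new = best_response(lqr2, plant.B2, u1, plant.B1)
        delta = max(np.abs(u1_new - u1).max(), np.abs(u2_new - u2).max())
        u1, u2 = u1_new, u2_new
        if delta < tol:
            break
    states = np.zeros((T, STATE_DIM))
    x = x0.copy()
    states[0] = x
    for t in range(1, T):
        x = plant.A @ x + plant.B1 @ u1[t - 1] + plant.B2 @ u2[t - 1]
        states[t] = x
    return {"u1_seq": u1, "u2_seq": u2, "states": states,
            "n_iter": n_iter, "converged": delta < tol, "delta": delta}


def simulate_closed_loop(plant: PlantModel, policies: PolicySet,
                         x0: np.ndarray | None = None,
                         seed: int | None = None,
                         with_noise: bool = False,
                         observers: tuple | None = None,
                         record_kwargs: dict | None = None) -> TrialRecord:
    """Roll out both players' policies on the plant for one trial.

    Without observers the controllers act on the true state (perfect
    state information).  With an ``(obs1, obs2)`` pair, each player's
    control is computed from that player's own posterior state estimate,
    and the observers are driven by their own noisy measurements.
    """
    T = policies.horizon_T
    if x0 is None:
        x0 = plant.initial_state()
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (STATE_DIM,):
        raise ValueError(f"x0 must have dimension {STATE_DIM}")
    rng = np.random.default_rng(seed)
    connected = plant.spring_k > 0

    states = np.zeros((T, STATE_DIM))
    u1s = np.zeros((T - 1, 2))
    u2s = np.zeros((T - 1, 2))
    est_u2 = np.zeros((T - 1, 2))
    est_u1 = np.zeros((T - 1, 2))
    x = x0.copy()
    states[0] = x
    for t in range(1, T):
        if observers is not None:
            x1_hat = observers[0].state_estimate()
            x2_hat = observers[1].state_estimate()
            est_u2[t - 1] = observers[0].partner_input_estimate()
            est_u1[t - 1] = observers[1].partner_input_estimate()
        else:
            x1_hat = x2_hat = x
        u1 = policies.control(1, t, x1_hat)
        u2 = policies.control(2, t, x2_hat)
        u1s[t - 1] = u1
        u2s[t - 1] = u2
        x = step_dynamics(plant, x, u1, u2, rng=rng if with_noise else None)
        if not np.all(np.abs(x) < 1e6):
            raise FloatingPointError(f"closed-loop state diverged at step {t}")
        states[t] = x
        if observers is not None:
            for obs, u_own in ((observers[0], u1), (observers[1], u2)):
                y = obs.measure(x, rng=rng if with_noise else None)
                obs.step(y, u_own)

    F = np.array([interaction_force(s, plant.spring_k)[0] for s in states])
    kwargs = dict(connected=connected, seed=seed)
    if record_kwargs:
        kwargs.update(record_kwargs)
    return TrialRecord(states=states, u1=u1s, u2=u2s, F1=F, F2=-F,
                       dt=plant.dt,
                       est_u2_by_1=est_u2 if observers is not None else None,
                       est_u1_by_2=est_u1 if observers is not None else None,
                       **kwargs)


def _trajectory_costs(plant: PlantModel, policies: PolicySet,
                      cost1: CostSpec, cost2: CostSpec,
                      x0: np.ndarray) -> tuple[float, float]:
    rec = simulate_closed_loop(plant, policies, x0=x0, with_noise=False)
    J1 = evaluate_cost(rec.states, rec.u1, cost1)
    J2 = evaluate_cost(rec.states, rec.u2, cost2)
    return J1, J2


def verify_nash(plant: PlantModel, cost1: CostSpec, cost2: CostSpec,
                policies: PolicySet, n_perturb: int = 200,
                magnitude: float = 0.05, seed: int | None = None) -> dict:
    """Monte-Carlo check of the Nash inequalities.

    For each player, draws random unilateral perturbations of that
    player's gain sequence, re-simulates the noiseless closed loop with
    the partner's policy fixed, and records the largest relative cost
    decrease the deviating player achieves.  For a Nash policy pair the
    maxima should not exceed ``NASH_REL_TOL``.

    Each perturbation touches the gain at one random time step, with a
    random direction and a log-uniformly drawn amplitude (relative to
    the gain-sequence RMS).  At a non-equilibrium policy the cost
    gradient with respect to some stage gain is non-zero, so
    small-amplitude draws expose an improvement linear in the amplitude;
    a feedback Nash policy is stagewise optimal against the partner's
    fixed policy and admits none.
    """
    rng = np.random.default_rng(seed)
    x0 = plant.initial_state()
    J1_base, J2_base = _trajectory_costs(plant, policies, cost1, cost2, x0)
    report = {"n_perturb": n_perturb, "magnitude": magnitude,
              "J1": J1_base, "J2": J2_base,
              "max_improvement": {1: 0.0, 2: 0.0}, "tol": NASH_REL_TOL}
    if n_perturb == 0:
        return report
    for player, (L_seq, J_base, cost) in {
        1: (policies.L1_seq, J1_base, cost1),
        2: (policies.L2_seq, J2_base, cost2),
    }.items():
        rms = np.sqrt(np.mean(L_seq**2))
        best = 0.0
        for _ in range(n_perturb):
            amp = magnitude * 10.0 ** rng.uniform(-4.0, 0.0)
            t_pert = rng.integers(L_seq.shape[0])
            direction = rng.standard_normal(L_seq.shape[1:])
            dL = np.zeros_like(L_seq)
            dL[t_pert] = direction * (amp * rms / np.sqrt(np.mean(direction**2)))
            dev = PolicySet(
                L1_seq=L_seq + dL if player == 1 else policies.L1_seq,
                L2_seq=L_seq + dL if player == 2 else policies.L2_seq,
                f1_seq=policies.f1_seq, f2_seq=policies.f2_seq,
                scenario="perturbed")
            try:
                J1, J2 = _trajectory_costs(plant, dev, cost1, cost2, x0)
            except FloatingPointError:
                continue  # diverged deviation: unboundedly worse, no improvement

            J_dev = J1 if player == 1 else J2
            improvement = (J_base - J_dev) / max(abs(J_base), 1e-300)
            best = max(best, improvement)
        report["max_improvement"][player] = best
    return report
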