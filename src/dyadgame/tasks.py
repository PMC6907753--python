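"""Quadratic task costs for the two players.

Each player's goal — pass through their own via-point, reach the target
and stop there, keep the coupling force low, and spend little effort —
is expressed as a finite-horizon quadratic cost

    J_i = sum_{t=1..T-1} [ x(t)' Q_i(t) x(t) + u_i(t)' R_i u_i(t) ]
          + x(T)' Q_i(T) x(T).

Because target and via-points are part of the state vector, errors such
as ``p_i - vp_i`` are linear in the state and every term is an exact
quadratic form.  The via-point requirement is imposed at a single
designated time step; the interaction-force requirement is a running
penalty on ``||p1 - p2||^2`` (the spring force is ``k (p1 - p2)``, so
this is the force magnitude up to the constant ``k^2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plant import IDX, STATE_DIM, PlantModel


#: default cost weights, calibrated once so that noiseless Nash rollouts
#: of the standard geometry pass within 5 mm of both via-points and stop
#: on the target (see docs/methods.md)
DEFAULT_WEIGHTS = {
    "w_vp": 1.0e4,      # via-point error, 1/m^2 at via_time
    "w_target": 1.0e4,  # terminal target error, 1/m^2
    "w_stop": 1.0e2,    # terminal velocity, s^2/m^2
    "w_force": 3.0e2,   # running inter-player distance, 1/m^2
    "w_effort": 1.0e-3, # control effort, 1/N^2
}

#: default via-point passage times as fractions of the horizon
DEFAULT_VIA_FRACTION = {1: 0.35, 2: 0.65}


def _diff_selector(a: str, b: str) -> np.ndarray:
    """2x22 matrix D with D x = x[a] - x[b]."""
    D = np.zeros((2, STATE_DIM))
    D[:, IDX[a]] = np.eye(2)
    D[:, IDX[b]] -= np.eye(2)
    return D


def _selector(a: str) -> np.ndarray:
    S = np.zeros((2, STATE_DIM))
    S[:, IDX[a]] = np.eye(2)
    return S


@dataclass
class CostSpec:
    """Per-player quadratic cost: per-step state weights plus effort weight."""

    player_id: int
    Q_seq: np.ndarray          # (T+1, 22, 22); Q_seq[0] unused (costs run t=1..T)
    R: np.ndarray              # (2, 2) positive definite
    T: int
    via_time: int
    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.player_id not in (1, 2):
            raise ValueError("player_id must be 1 or 2")
        if not (1 <= self.via_time < self.T):
            raise ValueError("via_time must lie strictly inside the horizon")
        R = np.asarray(self.R, dtype=float)
        if not np.allclose(R, R.T) or np.min(np.linalg.eigvalsh(R)) <= 0:
            raise ValueError("R must be symmetric positive definite")
        self.R = R


def build_cost(player_id: int, plant: PlantModel,
               weights: dict | None = None,
               T: int | None = None,
               via_time: int | None = None) -> CostSpec:
    """Construct one player's cost over the plant's horizon.

    ``Q(t)`` contains the running inter-player distance penalty at every
    step, the own-via-point penalty at ``via_time`` and the target +
    stopping penalty at the final step ``T``.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    if any(v < 0 for v in w.values()):
        raise ValueError("cost weights must be non-negative")
    if w["w_effort"] <= 0:
        raise ValueError("w_effort must be > 0")
    if T is None:
        T = plant.horizon_T
    if via_time is None:
        via_time = int(round(DEFAULT_VIA_FRACTION[player_id] * T))
    if not (0 < via_time < T):
        raise ValueError(f"via_time {via_time} outside (0, {T})")

    p, v, vp = (("p1", "v1", "vp1") if player_id == 1 else ("p2", "v2", "vp2"))
    D_vp = _diff_selector(p, vp)
    D_target = _diff_selector(p, "target")
    D_vel = _selector(v)
    D_dist = _diff_selector("p1", "p2")

    Q_run = w["w_force"] * D_dist.T @ D_dist
    Q_seq = np.broadcast_to(Q_run, (T + 1, STATE_DIM, STATE_DIM)).copy()
    Q_seq[0] = 0.0
    Q_seq[via_time] = Q_run + w["w_vp"] * D_vp.T @ D_vp
    Q_seq[T] = Q_run + w["w_target"] * D_target.T @ D_target + w["w_stop"] * D_vel.T @ D_vel
    return CostSpec(player_id=player_id, Q_seq=Q_seq, R=w["w_effort"] * np.eye(2),
                    T=T, via_time=via_time, weights=w)


def zero_cost(player_id: int, T: int, w_effort: float = 1.0) -> CostSpec:
    """A cost with no state terms (used for degenerate/oracle games)."""
    Q_seq = np.zeros((T + 1, STATE_DIM, STATE_DIM))
    return CostSpec(player_id=player_id, Q_seq=Q_seq, R=w_effort * np.eye(2),
                    T=T, via_time=max(1, T // 2), weights={"w_effort": w_effort})


def evaluate_cost(states: np.ndarray, controls: np.ndarray, spec: CostSpec) -> float:
    """Evaluate the quadratic cost on a rolled-out trajectory.

    ``states`` has shape (T, 22) with ``states[t-1] = x(t)`` for
    t = 1..T; ``controls`` has shape (T-1, 2) with
    ``controls[t-1] = u(t)`` for t = 1..T-1.  The running cost sums over
    t = 1..T-1 and the terminal cost uses ``Q_seq[T]`` at ``x(T)``.
    """
    states = np.asarray(states, dtype=float)
    controls = np.asarray(controls, dtype=float)
    T = spec.T
    if states.shape != (T, STATE_DIM):
        raise ValueError(f"states must have shape ({T}, {STATE_DIM})")
    if controls.shape != (T - 1, 2):
        raise ValueError(f"controls must have shape ({T - 1}, 2)")
    J = 0.0
    for t in range(1, T):
        x = states[t - 1]
        u = controls[t - 1]
        J += x @ spec.Q_seq[t] @ x + u @ spec.R @ u
    xT = states[T - 1]
    J += xT @ spec.Q_seq[T] @ xT
    return float(J)
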