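"""Discrete-time dyad plant: two point masses coupled by a spring.

Each player applies a planar force to their own point mass through a
muscle-like activation cascade (two first-order lags per axis).  The two
masses are connected by a linear spring of stiffness ``k``, so the force
on player 1 is ``-k (p1 - p2)`` and the force on player 2 is its exact
opposite.  For convenience the goal geometry (target and both via-points)
is appended to the state vector, giving a 22-dimensional state:

====================  =========  ==============================
block                 indices    meaning
====================  =========  ==============================
``p1``                0:2        player-1 position (m)
``v1``                2:4        player-1 velocity (m/s)
``a1``                4:8        player-1 activation (N, N)
``p2``, ``v2``,       8:16       same for player 2
``a2``
``target``            16:18      shared target position (m)
``vp1``               18:20      player-1 via-point (m)
``vp2``               20:22      player-2 via-point (m)
====================  =========  ==============================

The goal block has identity dynamics (it never changes during a trial);
it exists so that task errors such as ``p1 - vp1`` are linear in the
state and the costs stay purely quadratic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

STATE_DIM = 22
PLAYER_BLOCK_DIM = 8
GOAL_DIM = 6

#: index map for the state-vector blocks
IDX = {
    "p1": slice(0, 2),
    "v1": slice(2, 4),
    "f1": slice(4, 6),
    "g1": slice(6, 8),
    "p2": slice(8, 10),
    "v2": slice(10, 12),
    "f2": slice(12, 14),
    "g2": slice(14, 16),
    "target": slice(16, 18),
    "vp1": slice(18, 20),
    "vp2": slice(20, 22),
}

GROUPS = ("H", "VH", "PV")


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got {M.shape}")
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(M)) < -1e-12:
        raise ValueError(f"{name} must be positive semi-definite")
    return M


@dataclass
class DyadParams:
    """Physical parameters of the coupled two-player plant.

    Parameters
    ----------
    mass_per_player : float
        Point mass operated by each player, kg.
    spring_k : float
        Coupling-spring stiffness, N/m (0 disconnects the players).
    damping : float
        Viscous damping per player, N s/m — the intrinsic impedance of
        hand plus haptic handle.  Besides being physical, it bounds the
        after-effect transient when a policy planned on the coupled
        plant runs on a silently disconnected one (catch trials).
    dt : float
        Simulation / recording time step, s (0.01 s = 100 Hz).
    activation_tau : tuple of float
        Time constants of the two cascaded first-order activation
        filters, s.
    motor_noise_std : float
        Std of the additive Gaussian motor noise per force axis, N.
    horizon_T : int
        Number of discrete steps in one trial.
    """

    mass_per_player: float = 1.0
    spring_k: float = 150.0
    damping: float = 12.0
    dt: float = 0.01
    activation_tau: tuple[float, float] = (0.04, 0.04)
    motor_noise_std: float = 0.3
    horizon_T: int = 200
    motor_noise_cov_1: np.ndarray | None = None
    motor_noise_cov_2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mass_per_player <= 0:
            raise ValueError("mass_per_player must be > 0")
        if self.spring_k < 0:
            raise ValueError("spring_k must be >= 0")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.horizon_T < 2:
            raise ValueError("horizon_T must be >= 2")
        if any(tau <= 0 for tau in self.activation_tau):
            raise ValueError("activation time constants must be > 0")
        default = self.motor_noise_std**2 * np.eye(2)
        if self.motor_noise_cov_1 is None:
            self.motor_noise_cov_1 = default.copy()
        if self.motor_noise_cov_2 is None:
            self.motor_noise_cov_2 = default.copy()
        self.motor_noise_cov_1 = _check_psd(self.motor_noise_cov_1, "motor_noise_cov_1")
        self.motor_noise_cov_2 = _check_psd(self.motor_noise_cov_2, "motor_noise_cov_2")


@dataclass
class Geometry:
    """Workspace geometry (meters): start, target and the two via-points."""

    start: np.ndarray = field(default_factory=lambda: np.array([-0.05, 0.0]))
    target: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.0]))
    vp1: np.ndarray = field(default_factory=lambda: np.array([-0.03, -0.02]))
    vp2: np.ndarray = field(default_factory=lambda: np.array([0.03, 0.02]))

    def __post_init__(self) -> None:
        for name in ("start", "target", "vp1", "vp2"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (2,):
                raise ValueError(f"geometry.{name} must be a 2-vector")
            setattr(self, name, v)


@dataclass
class PlantModel:
    """Discretized dyad dynamics ``x(t+1) = A x + B1 (u1+eta1) + B2 (u2+eta2)``."""

    A: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    A_cont: np.ndarray
    params: DyadParams
    geometry: Geometry
    idx: dict = field(default_factory=lambda: dict(IDX))

    @property
    def dt(self) -> float:
        return self.params.dt

    @property
    def spring_k(self) -> float:
        return self.params.spring_k

    @property
    def horizon_T(self) -> int:
        return self.params.horizon_T

    def initial_state(self) -> np.ndarray:
        """Both players at rest on the start point; goal block filled in."""
        x = np.zeros(STATE_DIM)
        g = self.geometry
        x[IDX["p1"]] = g.start
        x[IDX["p2"]] = g.start
        x[IDX["target"]] = g.target
        x[IDX["vp1"]] = g.vp1
        x[IDX["vp2"]] = g.vp2
        return x

    def disconnected(self) -> "PlantModel":
        """The same plant with the coupling spring removed (k = 0)."""
        return build_plant(replace(self.params, spring_k=0.0,
                                   motor_noise_cov_1=self.params.motor_noise_cov_1,
                                   motor_noise_cov_2=self.params.motor_noise_cov_2),
                           self.geometry)


def _continuous_matrices(params: DyadParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = params.mass_per_player
    k = params.spring_k
    b = params.damping
    tau1, tau2 = params.activation_tau
    A = np.zeros((STATE_DIM, STATE_DIM))
    B1 = np.zeros((STATE_DIM, 2))
    B2 = np.zeros((STATE_DIM, 2))
    I2 = np.eye(2)
    for i, (p, v, f, g, p_other) in enumerate(
        [("p1", "v1", "f1", "g1", "p2"), ("p2", "v2", "f2", "g2", "p1")]
    ):
        A[IDX[p], IDX[v]] = I2
        # mass acceleration: activation force + viscous drag + spring -k(p_i - p_-i)
        A[IDX[v], IDX[f]] = I2 / m
        A[IDX[v], IDX[v]] += -b / m * I2
        A[IDX[v], IDX[p]] += -k / m * I2
        A[IDX[v], IDX[p_other]] += k / m * I2
        # activation cascade: u -> g -> f
        A[IDX[f], IDX[f]] = -I2 / tau1
        A[IDX[f], IDX[g]] = I2 / tau1
        A[IDX[g], IDX[g]] = -I2 / tau2
        B = B1 if i == 0 else B2
        B[IDX[g], :] = I2 / tau2
    # goal block: zero continuous dynamics (constant)
    return A, B1, B2


def build_plant(params: DyadParams, geometry: Geometry | None = None,
                method: str = "zoh") -> PlantModel:
    """Build the discrete-time dyad plant.

    Parameters
    ----------
    params : DyadParams
    geometry : Geometry, optional
        Start/target/via-point layout; defaults to the standard task.
    method : {"zoh", "euler"}
        Discretization scheme.  Zero-order hold is exact for the linear
        continuous dynamics; forward Euler is provided for comparison.
    """
    if geometry is None:
        geometry = Geometry()
    Ac, B1c, B2c = _continuous_matrices(params)
    n, mdim = STATE_DIM, 4
    if method == "zoh":
        Bc = np.hstack([B1c, B2c])
        M = np.zeros((n + mdim, n + mdim))
        M[:n, :n] = Ac
        M[:n, n:] = Bc
        Md = expm(M * params.dt)
        A = Md[:n, :n]
        Bd = Md[:n, n:]
        B1, B2 = Bd[:, :2], Bd[:, 2:]
    elif method == "euler":
        A = np.eye(n) + params.dt * Ac
        B1 = params.dt * B1c
        B2 = params.dt * B2c
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    return PlantModel(A=A, B1=B1, B2=B2, A_cont=Ac, params=params, geometry=geometry)


def step_dynamics(plant: PlantModel, x: np.ndarray, u1: np.ndarray, u2: np.ndarray,
                  noise: tuple[np.ndarray, np.ndarray] | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """One step of ``x(t+1) = A x + B1 (u1+eta1) + B2 (u2+eta2)``.

    Motor noise is taken from ``noise = (eta1, eta2)`` if given, drawn
    from the plant's motor-noise covariances if ``rng`` is given, and
    zero otherwise.
    """
    x = np.asarray(x, dtype=float)
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if x.shape != (STATE_DIM,):
        raise ValueError(f"state must have dimension {STATE_DIM}")
    if u1.shape != (2,) or u2.shape != (2,):
        raise ValueError("controls must be 2-vectors")
    if not (np.all(np.isfinite(u1)) and np.all(np.isfinite(u2))):
        raise ValueError("controls must be finite")
    if noise is not None:
        eta1, eta2 = (np.asarray(e, dtype=float) for e in noise)
    elif rng is not None:
        eta1 = rng.multivariate_normal(np.zeros(2), plant.params.motor_noise_cov_1)
        eta2 = rng.multivariate_normal(np.zeros(2), plant.params.motor_noise_cov_2)
    else:
        eta1 = eta2 = np.zeros(2)
    return plant.A @ x + plant.B1 @ (u1 + eta1) + plant.B2 @ (u2 + eta2)


def interaction_force(x: np.ndarray, k: float) -> tuple[np.ndarray, np.ndarray]:
    """Spring forces on the two players: ``F1 = -k (p1 - p2)``, ``F2 = -F1``."""
    if k < 0:
        raise ValueError("spring stiffness must be >= 0")
    x = np.asarray(x, dtype=float)
    d = x[IDX["p1"]] - x[IDX["p2"]]
    F1 = -k * d
    return F1, -F1


# ---------------------------------------------------------------------------
# sensory models

#: default per-channel measurement noise stds; units are meters, m/s or N
DEFAULT_NOISE_PROFILES = {
    "H": {"pos": 0.005, "vel": 0.01, "via_point": 0.001, "target": 0.001,
          "force": 1.0},
    "VH": {"pos": 0.005, "vel": 0.01, "via_point": 0.001, "target": 0.001,
           "force": 0.3},
    "PV": {"pos": 0.005, "vel": 0.01, "via_point": 0.001, "target": 0.001,
           "force": 1.0, "partner_pos": 0.001},
}


@dataclass
class SensoryModel:
    """Linear-Gaussian measurement model ``y = H_obs x + v`` for one player.

    The channel set encodes the experimental group: H and VH observe own
    kinematics, the goal block and the interaction force (VH with a
    smaller force noise, since the force vector is also displayed); PV
    additionally observes the partner's position directly.
    """

    group: str
    player_id: int
    H_obs: np.ndarray
    noise_std: np.ndarray
    channels: list[str]

    @property
    def n_channels(self) -> int:
        return self.H_obs.shape[0]

    @property
    def noise_cov(self) -> np.ndarray:
        return np.diag(self.noise_std**2)


def build_sensory_model(group: str, plant: PlantModel, player_id: int = 1,
                        noise_profile: dict | None = None) -> SensoryModel:
    """Assemble the observation matrix and noise for one player of a group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if player_id not in (1, 2):
        raise ValueError("player_id must be 1 or 2")
    profile = dict(DEFAULT_NOISE_PROFILES[group])
    if noise_profile:
        profile.update(noise_profile)
    p_own, v_own, vp_own, p_other = (("p1", "v1", "vp1", "p2") if player_id == 1
                                     else ("p2", "v2", "vp2", "p1"))

    rows, stds, labels = [], [], []

    def add(block_rows: np.ndarray, std: float, label: str) -> None:
        rows.append(block_rows)
        stds.extend([std, std])
        labels.extend([f"{label}_x", f"{label}_y"])

    def selector(name: str) -> np.ndarray:
        S = np.zeros((2, STATE_DIM))
        S[:, IDX[name]] = np.eye(2)
        return S

    add(selector(p_own), profile["pos"], "own_position")
    add(selector(v_own), profile["vel"], "own_velocity")
    add(selector(vp_own), profile["via_point"], "own_via_point")
    add(selector("target"), profile["target"], "target")
    # interaction force on this player: k (p_other - p_own)
    k = plant.spring_k
    add(k * (selector(p_other) - selector(p_own)), profile["force"], "interaction_force")
    if group == "PV":
        add(selector(p_other), profile["partner_pos"], "partner_position")
    H_obs = np.vstack(rows)
    return SensoryModel(group=group, player_id=player_id, H_obs=H_obs,
                        noise_std=np.array(stds), channels=labels)


def observe(sensory: SensoryModel, x: np.ndarray,
            noise: np.ndarray | None = None,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Noisy measurement ``H_obs x + v``; deterministic given a seeded rng."""
    x = np.asarray(x, dtype=float)
    if x.shape != (STATE_DIM,):
        raise ValueError(f"state must have dimension {STATE_DIM}")
    y = sensory.H_obs @ x
    if noise is not None:
        noise = np.asarray(noise, dtype=float)
        if noise.shape != y.shape:
            raise ValueError("noise draw has wrong dimension")
        return y + noise
    if rng is not None:
        return y + rng.standard_normal(y.shape) * sensory.noise_std
    return y
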