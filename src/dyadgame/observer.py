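"""Per-player state observer with partner-command estimation.

Each player runs a Kalman filter on an *augmented* plant whose state is
``X = [x; u_partner]`` (22 + 2 = 24 dimensions).  The partner's command
is modelled as a slowly varying latent input,

    u_partner(t+1) = A_u * u_partner(t) + eps(t),   0 < A_u < 1,

i.e. a low-pass-filtered Gaussian process.  Prediction combines the
dyad forward model with the efference copy of the player's own command;
correction uses that player's own (group-specific) sensory channels.
The filter therefore delivers both a posterior dyad-state estimate and
a posterior estimate of what the partner is currently doing — the
"partner model" that drives fictitious-play learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plant import STATE_DIM, PlantModel, SensoryModel, observe

AUG_DIM = STATE_DIM + 2

#: default partner-input prior: decay per 10 ms step, and innovation std (N).
#: Per-sample kinematic measurements carry little information about a ~1 N
#: input, so the prior must be smooth enough to integrate over many samples
#: without shrinking a sustained input to zero (see docs/methods.md).
DEFAULT_A_U = 0.99
DEFAULT_SIGMA_EPS = 0.5
#: default prior variance on the partner-input block (N^2)
DEFAULT_U_PRIOR_VAR = 25.0


@dataclass
class AugmentedModel:
    """Augmented linear-Gaussian model seen by one player's observer."""

    player_id: int
    A_aug: np.ndarray        # (24, 24)
    B_aug: np.ndarray        # (24, 2) own-input map
    Sigma_w: np.ndarray      # (24, 24) process noise covariance
    A_u: float
    Sigma_eps: np.ndarray    # (2, 2)


@dataclass
class ObserverState:
    """Posterior estimate ``X_hat = [x_hat; u_partner_hat]`` and covariance."""

    X_hat: np.ndarray
    P: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        if self.X_hat.shape != (AUG_DIM,):
            raise ValueError(f"X_hat must have dimension {AUG_DIM}")
        if self.P.shape != (AUG_DIM, AUG_DIM):
            raise ValueError("P must be 24x24")


#: default std of the diagonal model-uncertainty floor added to the process
#: noise of the 22 plant states (per 10 ms step).  Without it the filter is
#: absolutely certain of the forward model away from the input channels, and
#: any dynamics mismatch (e.g. a silently removed coupling spring on a catch
#: trial) destabilizes the estimate-driven closed loop.
DEFAULT_PROCESS_FLOOR = 1e-3


def build_augmented(plant: PlantModel, player_id: int,
                    A_u: float = DEFAULT_A_U,
                    Sigma_eps: np.ndarray | None = None,
                    process_floor: float = DEFAULT_PROCESS_FLOOR) -> AugmentedModel:
    """Assemble the partner-input-augmented transition for one player."""
    if not (0.0 < A_u < 1.0):
        raise ValueError("A_u must lie strictly in (0, 1)")
    if Sigma_eps is None:
        Sigma_eps = DEFAULT_SIGMA_EPS**2 * np.eye(2)
    Sigma_eps = np.asarray(Sigma_eps, dtype=float)
    if Sigma_eps.shape != (2, 2) or np.min(np.linalg.eigvalsh(Sigma_eps)) < -1e-12:
        raise ValueError("Sigma_eps must be a 2x2 PSD matrix")
    if player_id == 1:
        B_own, B_other = plant.B1, plant.B2
        Sigma_eta = plant.params.motor_noise_cov_1
    elif player_id == 2:
        B_own, B_other = plant.B2, plant.B1
        Sigma_eta = plant.params.motor_noise_cov_2
    else:
        raise ValueError("player_id must be 1 or 2")
    A_aug = np.zeros((AUG_DIM, AUG_DIM))
    A_aug[:STATE_DIM, :STATE_DIM] = plant.A
    A_aug[:STATE_DIM, STATE_DIM:] = B_other * A_u
    A_aug[STATE_DIM:, STATE_DIM:] = A_u * np.eye(2)
    B_aug = np.zeros((AUG_DIM, 2))
    B_aug[:STATE_DIM] = B_own
    Sigma_w = np.zeros((AUG_DIM, AUG_DIM))
    Sigma_w[:STATE_DIM, :STATE_DIM] = B_own @ Sigma_eta @ B_own.T
    # model-uncertainty floor on the dynamic states only; the goal block is
    # static and displayed, so the player's model of it is exact
    n_dyn = 2 * 8
    Sigma_w[:n_dyn, :n_dyn] += process_floor**2 * np.eye(n_dyn)
    Sigma_w[STATE_DIM:, STATE_DIM:] = Sigma_eps
    return AugmentedModel(player_id=player_id, A_aug=A_aug, B_aug=B_aug,
                          Sigma_w=Sigma_w, A_u=A_u, Sigma_eps=Sigma_eps)


def augment_sensory_map(sensory: SensoryModel) -> np.ndarray:
    """Observation matrix over the augmented state (input block unobserved)."""
    H = np.zeros((sensory.n_channels, AUG_DIM))
    H[:, :STATE_DIM] = sensory.H_obs
    return H


def _gain(P_minus: np.ndarray, H: np.ndarray, R: np.ndarray) -> np.ndarray:
    S = H @ P_minus @ H.T + R
    PHt = P_minus @ H.T
    try:
        return np.linalg.solve(S.T, PHt.T).T
    except np.linalg.LinAlgError:
        # degenerate (noise-free) channels: minimum-norm gain
        return PHt @ np.linalg.pinv(S, hermitian=True)


def _joseph(P_minus: np.ndarray, K: np.ndarray, H: np.ndarray,
            R: np.ndarray) -> np.ndarray:
    IKH = np.eye(AUG_DIM) - K @ H
    P = IKH @ P_minus @ IKH.T + K @ R @ K.T
    return 0.5 * (P + P.T)


def kalman_gain_schedule(aug: AugmentedModel, sensory: SensoryModel,
                         P0: np.ndarray, T: int,
                         return_priors: bool = False):
    """Time-varying Kalman gains over a horizon.

    Runs the forward covariance recursion (predict with the augmented
    dynamics, correct with the player's sensory map; Joseph-form update)
    and returns ``(K_seq, P_seq)`` with one gain per correction,
    ``K_seq[t]`` applying at step t+1.  Gains do not depend on the data,
    so one schedule can be reused across trials.  With
    ``return_priors=True`` the pre-correction covariances are returned
    as well (needed by the backward smoothing pass).
    """
    P0 = np.asarray(P0, dtype=float)
    if np.min(np.linalg.eigvalsh(0.5 * (P0 + P0.T))) < -1e-10:
        raise ValueError("P0 must be PSD")
    H = augment_sensory_map(sensory)
    R = sensory.noise_cov
    n_y = sensory.n_channels
    P = P0.copy()
    K_seq = np.zeros((T, AUG_DIM, n_y))
    P_seq = np.zeros((T, AUG_DIM, AUG_DIM))
    P_prior_seq = np.zeros((T, AUG_DIM, AUG_DIM))
    for t in range(T):
        P_minus = aug.A_aug @ P @ aug.A_aug.T + aug.Sigma_w
        K = _gain(P_minus, H, R)
        if not np.all(np.isfinite(K)):
            raise FloatingPointError(f"singular innovation covariance at step {t}")
        P = _joseph(P_minus, K, H, R)
        K_seq[t] = K
        P_seq[t] = P
        P_prior_seq[t] = P_minus
    if return_priors:
        return K_seq, P_seq, P_prior_seq
    return K_seq, P_seq


def smoother_gain_schedule(aug: AugmentedModel, P_post: np.ndarray,
                           P_prior: np.ndarray) -> np.ndarray:
    """Backward (RTS) smoother gains ``G[t] = P+_t A' (P-_{t+1})^-1``.

    Like the filter gains these are data independent, so one schedule
    per sensory configuration serves every trial.
    """
    T = P_post.shape[0]
    G = np.zeros((T - 1, AUG_DIM, AUG_DIM))
    for t in range(T - 1):
        G[t] = P_post[t] @ aug.A_aug.T @ np.linalg.pinv(P_prior[t + 1],
                                                        hermitian=True)
    return G


def observer_step(obs: ObserverState, aug: AugmentedModel, sensory: SensoryModel,
                  y: np.ndarray, u_own: np.ndarray) -> ObserverState:
    """One predict + correct cycle of the augmented Kalman filter."""
    y = np.asarray(y, dtype=float)
    if y.shape != (sensory.n_channels,):
        raise ValueError("measurement dimension mismatch")
    u_own = np.asarray(u_own, dtype=float)
    if u_own.shape != (2,):
        raise ValueError("own control must be a 2-vector")
    H = augment_sensory_map(sensory)
    R = sensory.noise_cov
    X_minus = aug.A_aug @ obs.X_hat + aug.B_aug @ u_own
    P_minus = aug.A_aug @ obs.P @ aug.A_aug.T + aug.Sigma_w
    K = _gain(P_minus, H, R)
    X_plus = X_minus + K @ (y - H @ X_minus)
    P_plus = _joseph(P_minus, K, H, R)
    return ObserverState(X_hat=X_plus, P=P_plus, step=obs.step + 1)


def extract_partner_input(obs: ObserverState) -> np.ndarray:
    """The partner-command block of the augmented estimate."""
    return obs.X_hat[STATE_DIM:].copy()


def initial_observer_state(plant: PlantModel, x0: np.ndarray | None = None,
                           u_prior_var: float = DEFAULT_U_PRIOR_VAR,
                           p0_scale: float = 1e-6) -> ObserverState:
    """Prior at trial start.

    The kinematic blocks start at the true start state and the goal
    block at the displayed goal positions (both known to the player, so
    tiny prior variance); the partner-input block starts at zero with a
    wide prior.
    """
    if x0 is None:
        x0 = plant.initial_state()
    X0 = np.concatenate([np.asarray(x0, dtype=float), np.zeros(2)])
    P0 = p0_scale * np.eye(AUG_DIM)
    P0[STATE_DIM:, STATE_DIM:] = u_prior_var * np.eye(2)
    return ObserverState(X_hat=X0, P=P0)


class KalmanObserver:
    """Stateful wrapper pairing an augmented model with a sensory stream.

    Used by the closed-loop simulator: ``measure`` draws the player's
    noisy measurement of the true state, ``step`` advances the filter.
    """

    def __init__(self, plant: PlantModel, sensory: SensoryModel,
                 A_u: float = DEFAULT_A_U,
                 Sigma_eps: np.ndarray | None = None,
                 x0: np.ndarray | None = None,
                 u_prior_var: float = DEFAULT_U_PRIOR_VAR,
                 K_seq: np.ndarray | None = None,
                 process_floor: float = DEFAULT_PROCESS_FLOOR):
        self.aug = build_augmented(plant, sensory.player_id, A_u, Sigma_eps,
                                   process_floor=process_floor)
        self.sensory = sensory
        self._init_args = (plant, x0, u_prior_var)
        self.state = initial_observer_state(plant, x0, u_prior_var)
        # gains are data-independent, so a schedule precomputed with
        # kalman_gain_schedule can be shared across trials
        self.K_seq = K_seq
        self._H_aug = augment_sensory_map(sensory)
        #: RTS smoother gains (set to enable smoothed_partner_inputs)
        self.G_seq: np.ndarray | None = None
        self.record_history = False
        self._Xm: list[np.ndarray] = []
        self._Xp: list[np.ndarray] = []

    def reset(self) -> None:
        plant, x0, u_prior_var = self._init_args
        self.state = initial_observer_state(plant, x0, u_prior_var)
        self._Xm, self._Xp = [], []

    def measure(self, x_true: np.ndarray,
                rng: np.random.Generator | None = None) -> np.ndarray:
        return observe(self.sensory, x_true, rng=rng)

    def step(self, y: np.ndarray, u_own: np.ndarray) -> None:
        if self.K_seq is not None and self.state.step < len(self.K_seq):
            X_minus = self.aug.A_aug @ self.state.X_hat + self.aug.B_aug @ u_own
            K = self.K_seq[self.state.step]
            X_plus = X_minus + K @ (y - self._H_aug @ X_minus)
            self.state = ObserverState(X_hat=X_plus, P=self.state.P,
                                       step=self.state.step + 1)
        else:
            X_minus = self.aug.A_aug @ self.state.X_hat + self.aug.B_aug @ u_own
            self.state = observer_step(self.state, self.aug, self.sensory, y, u_own)
            X_plus = self.state.X_hat
        if self.record_history:
            self._Xm.append(X_minus)
            self._Xp.append(X_plus.copy())

    def smoothed_partner_inputs(self) -> np.ndarray:
        """RTS-smoothed partner-command series over the recorded trial.

        The forward filter is causal and therefore lags the partner's
        command; between trials the whole trial's data are available, so
        the backward pass removes that lag.  Requires ``record_history``
        and a precomputed ``G_seq``.  Returns the smoothed estimate of
        ``u_partner(t)`` for each recorded step.
        """
        if not self._Xp:
            raise RuntimeError("no recorded history to smooth")
        if self.G_seq is None:
            raise RuntimeError("smoother gains G_seq not set")
        n = len(self._Xp)
        Xs = self._Xp[-1].copy()
        out = np.zeros((n, 2))
        out[-1] = Xs[STATE_DIM:]
        for t in range(n - 2, -1, -1):
            Xs = self._Xp[t] + self.G_seq[t] @ (Xs - self._Xm[t + 1])
            out[t] = Xs[STATE_DIM:]
        return out

    def state_estimate(self) -> np.ndarray:
        return self.state.X_hat[:STATE_DIM].copy()

    def partner_input_estimate(self) -> np.ndarray:
        return extract_partner_input(self.state)
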