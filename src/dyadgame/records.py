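"""Containers for simulated trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plant import IDX


@dataclass
class TrialRecord:
    """Time series of one movement (both players), sampled at the plant rate.

    ``states`` holds x(t) for t = 1..T (shape (T, 22)); controls hold
    u(t) for t = 1..T-1.  ``F1``/``F2`` are the spring forces actually
    applied during the trial (identically zero when disconnected).
    Optional per-player observer output (the estimated partner command
    series) is kept for the fictitious-play loop.
    """

    states: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    dt: float
    trial_index: int = 0
    phase: str = "training"
    connected: bool = True
    catch: bool = False
    seed: int | None = None
    est_u2_by_1: np.ndarray | None = None
    est_u1_by_2: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = self.states.shape[0]
        if self.F1.shape[0] != T or self.F2.shape[0] != T:
            raise ValueError("force series length must match state series")
        if self.u1.shape[0] != T - 1 or self.u2.shape[0] != T - 1:
            raise ValueError("control series must have length T-1")
        if not self.connected and (np.any(self.F1 != 0) or np.any(self.F2 != 0)):
            raise ValueError("disconnected trial must record zero forces")

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.T) * self.dt

    def positions(self, player: int) -> np.ndarray:
        return self.states[:, IDX["p1" if player == 1 else "p2"]]

    def velocities(self, player: int) -> np.ndarray:
        return self.states[:, IDX["v1" if player == 1 else "v2"]]
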