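"""Behavioral indicators for dyadic via-point reaching.

The pipeline mirrors a standard motor-control analysis chain applied
identically to simulated and recorded trials, all in the X-Y plane:

1. Savitzky-Golay smoothing (order 4, 370 ms window at 100 Hz) of the
   position traces; velocity and acceleration from the same local fits.
2. Movement segmentation at a 2 cm/s speed threshold.
3. Per-trial indicators:
   * score — logistic in d = d_VP + c * d12 (c = 0.5 connected, 0
     disconnected), saturating at 100 for d <= 5 mm and 0 for d >= 2 cm;
   * IF — trial-averaged interaction-force magnitude;
   * MD_ij — minimum distance of player i's path to via-point j;
   * P_i — interaction power F_i . v_i (negative = the player pushes
     against the coupling, a "leader"; positive = is pulled along, a
     "follower");
   * LI_ij — mean power of player i in the 300 ms before via-point j is
     crossed by its homologous player; role contrasts
     dLI_1 = LI_21 - LI_11 and dLI_2 = LI_12 - LI_22.
4. Epoch aggregation (12-trial means, catch trials excluded from
   connected-phase means).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .records import TrialRecord

SG_WINDOW = 37          # samples: 370 ms at 100 Hz
SG_ORDER = 4
SPEED_THRESHOLD = 0.02  # m/s
LI_WINDOW_S = 0.3       # s


class NoMovementError(ValueError):
    """Speed never exceeded the segmentation threshold."""


@dataclass
class ScoreParams:
    """Logistic score calibration.

    The logistic 100 / (1 + exp(h (d - d0))) cannot literally attain
    100 or 0; with d0 at the midpoint of the stated saturation band
    [5 mm, 20 mm] and h = 800 /m the displayed (integer-rounded) score
    is 100 at d = 5 mm and 0 at d = 20 mm, and exactly 50 at d0.
    """

    h: float = 800.0
    d0: float = 0.0125
    c_connected: float = 0.5
    d_max_score: float = 0.005
    d_min_score: float = 0.02

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if not (self.d_max_score < self.d0 < self.d_min_score):
            raise ValueError("d0 must lie between the saturation distances")


@dataclass
class IndicatorRow:
    """Per-trial indicator values (one trial of one dyad)."""

    trial: int
    score1: float
    score2: float
    IF: float
    MD11: float
    MD12: float
    MD21: float
    MD22: float
    LI11: float
    LI12: float
    LI21: float
    LI22: float
    dLI1: float
    dLI2: float
    duration: float

    def as_dict(self) -> dict:
        return asdict(self)


INDICATOR_NAMES = ["score1", "score2", "IF", "MD11", "MD12", "MD21", "MD22",
                   "LI11", "LI12", "LI21", "LI22", "dLI1", "dLI2", "duration"]


def smooth_and_differentiate(positions: np.ndarray, dt: float = 0.01,
                             window: int = SG_WINDOW, order: int = SG_ORDER
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Savitzky-Golay smoothing with derivatives from the same fits."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        positions = positions[:, None]
    if positions.shape[0] < window:
        raise ValueError(
            f"need at least {window} samples for the smoothing window, "
            f"got {positions.shape[0]}")
    pos = savgol_filter(positions, window, order, deriv=0, axis=0)
    vel = savgol_filter(positions, window, order, deriv=1, delta=dt, axis=0)
    acc = savgol_filter(positions, window, order, deriv=2, delta=dt, axis=0)
    return pos, vel, acc


def segment_movement(speed: np.ndarray,
                     threshold: float = SPEED_THRESHOLD) -> tuple[int, int]:
    """First and last sample at or above the speed threshold."""
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    above = np.flatnonzero(speed >= threshold)
    if above.size == 0:
        raise NoMovementError(
            f"speed never reached the {threshold} m/s threshold")
    return int(above[0]), int(above[-1])


def score_from_distance(d: float, params: ScoreParams) -> float:
    return 100.0 / (1.0 + math.exp(params.h * (d - params.d0)))


def compute_score(traj_i: np.ndarray, partner_traj: np.ndarray | None,
                  own_vp: np.ndarray, params: ScoreParams,
                  connected: bool) -> float:
    """Trial score of one player (continuous; round for display).

    ``d = d_VP + c * d12`` where d_VP is the minimum distance of the
    player's (segmented) path to their own via-point and d12 the mean
    inter-player distance over the movement; c = 0 when disconnected.
    """
    traj_i = np.asarray(traj_i, dtype=float)
    if traj_i.size == 0:
        raise ValueError("empty movement window")
    d_vp = compute_MD(traj_i, own_vp)
    c = params.c_connected if connected else 0.0
    d12 = 0.0
    if c != 0.0:
        if partner_traj is None:
            raise ValueError("connected score needs the partner trajectory")
        partner_traj = np.asarray(partner_traj, dtype=float)
        if partner_traj.shape != traj_i.shape:
            raise ValueError("partner trajectory must match the movement window")
        d12 = float(np.mean(np.linalg.norm(traj_i - partner_traj, axis=1)))
    return score_from_distance(d_vp + c * d12, params)


def compute_IF(forces: np.ndarray) -> float:
    """Mean Euclidean norm of the planar interaction force, N."""
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise ValueError("empty movement window")
    return float(np.mean(np.linalg.norm(forces, axis=1)))


def compute_MD(traj: np.ndarray, vp: np.ndarray) -> float:
    """Minimum distance of a sampled path to a via-point, m."""
    traj = np.asarray(traj, dtype=float)
    if traj.size == 0:
        raise ValueError("empty movement window")
    return float(np.min(np.linalg.norm(traj - np.asarray(vp, dtype=float), axis=1)))


def compute_power(F: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Interaction power P(t) = F(t) . v(t), W (per sample)."""
    F = np.asarray(F, dtype=float)
    v = np.asarray(v, dtype=float)
    if F.shape != v.shape:
        raise ValueError("force and velocity series must have equal shapes")
    return np.einsum("ij,ij->i", F, v)


def via_crossing_index(traj_homologous: np.ndarray, vp: np.ndarray) -> int:
    """Sample (within the movement window) at which the via-point's own
    player passes closest to it — the operational 'crossing' time."""
    traj = np.asarray(traj_homologous, dtype=float)
    return int(np.argmin(np.linalg.norm(traj - np.asarray(vp, dtype=float), axis=1)))


def compute_LI(power: np.ndarray, crossing_idx: int, dt: float = 0.01,
               window_s: float = LI_WINDOW_S) -> float:
    """Mean power over the ``window_s`` interval ending at the crossing.

    A crossing earlier than the window start truncates the window to
    the available samples; a crossing before the movement start is
    rejected.
    """
    power = np.asarray(power, dtype=float)
    if not (0 <= crossing_idx < power.shape[0]):
        raise ValueError("crossing index outside the movement window")
    n_win = max(1, int(round(window_s / dt)))
    lo = max(0, crossing_idx - n_win + 1)
    return float(np.mean(power[lo:crossing_idx + 1]))


def trial_indicators(rec: TrialRecord, vp1: np.ndarray, vp2: np.ndarray,
                     params: ScoreParams | None = None,
                     smooth: bool = True) -> IndicatorRow:
    """Run the full pipeline on one trial.

    The movement window is the union of the two players' segmented
    windows (earliest start to latest end), so that dyad-level
    quantities (IF, d12) and both players' indicators share one window.
    """
    if params is None:
        params = ScoreParams()
    dt = rec.dt
    if smooth:
        p1, v1, _ = smooth_and_differentiate(rec.positions(1), dt)
        p2, v2, _ = smooth_and_differentiate(rec.positions(2), dt)
        F1 = savgol_filter(rec.F1, SG_WINDOW, SG_ORDER, axis=0)
        F2 = savgol_filter(rec.F2, SG_WINDOW, SG_ORDER, axis=0)
    else:
        p1, v1 = rec.positions(1), rec.velocities(1)
        p2, v2 = rec.positions(2), rec.velocities(2)
        F1, F2 = rec.F1, rec.F2
    s1, e1 = segment_movement(np.linalg.norm(v1, axis=1))
    s2, e2 = segment_movement(np.linalg.norm(v2, axis=1))
    lo, hi = min(s1, s2), max(e1, e2) + 1

    p1w, p2w = p1[lo:hi], p2[lo:hi]
    v1w, v2w = v1[lo:hi], v2[lo:hi]
    F1w, F2w = F1[lo:hi], F2[lo:hi]

    score1 = compute_score(p1w, p2w, vp1, params, rec.connected)
    score2 = compute_score(p2w, p1w, vp2, params, rec.connected)
    IF = compute_IF(F1w)
    MD = {(i, j): compute_MD(pw, vp)
          for i, pw in ((1, p1w), (2, p2w))
          for j, vp in ((1, vp1), (2, vp2))}
    P1 = compute_power(F1w, v1w)
    P2 = compute_power(F2w, v2w)
    t_star = {1: via_crossing_index(p1w, vp1), 2: via_crossing_index(p2w, vp2)}
    LI = {(i, j): compute_LI(P, t_star[j], dt)
          for i, P in ((1, P1), (2, P2)) for j in (1, 2)}
    return IndicatorRow(
        trial=rec.trial_index,
        score1=score1, score2=score2, IF=IF,
        MD11=MD[(1, 1)], MD12=MD[(1, 2)], MD21=MD[(2, 1)], MD22=MD[(2, 2)],
        LI11=LI[(1, 1)], LI12=LI[(1, 2)], LI21=LI[(2, 1)], LI22=LI[(2, 2)],
        dLI1=LI[(2, 1)] - LI[(1, 1)], dLI2=LI[(1, 2)] - LI[(2, 2)],
        duration=(hi - lo) * dt)


def session_indicators(records, vp1, vp2, params: ScoreParams | None = None
                       ) -> pd.DataFrame:
    """Indicator table (one row per trial) for a sequence of trials."""
    rows = [trial_indicators(r, vp1, vp2, params).as_dict() for r in records]
    return pd.DataFrame(rows)


def aggregate_epochs(rows: pd.DataFrame, protocol) -> pd.DataFrame:
    """12-trial epoch means, excluding catch trials from connected epochs.

    Adds a ``stage`` label marking the early (1st), middle (6th) and
    late (10th) training epochs used for the time-course summary.
    """
    table = pd.DataFrame(protocol.trial_table())
    merged = rows.merge(table, on="trial")
    keep = merged[~((merged["phase"] == "training") & merged["catch"])]
    means = keep.groupby("epoch")[INDICATOR_NAMES].mean()
    means["phase"] = [protocol.epochs[e].phase for e in means.index]
    training_epochs = [e for e, ep in enumerate(protocol.epochs)
                       if ep.phase == "training"]
    stage = {}
    if training_epochs:
        stage[training_epochs[0]] = "early"
        stage[training_epochs[len(training_epochs) // 2]] = "middle"
        stage[training_epochs[-1]] = "late"
    means["stage"] = [stage.get(e, "") for e in means.index]
    return means


# ---------------------------------------------------------------------------
# trial CSV round-trip

TRIAL_CSV_COLUMNS = ["t", "p1x", "p1y", "p2x", "p2y",
                     "f1x", "f1y", "f2x", "f2y"]


def trial_to_frame(rec: TrialRecord) -> pd.DataFrame:
    p1, p2 = rec.positions(1), rec.positions(2)
    return pd.DataFrame({
        "t": rec.t,
        "p1x": p1[:, 0], "p1y": p1[:, 1],
        "p2x": p2[:, 0], "p2y": p2[:, 1],
        "f1x": rec.F1[:, 0], "f1y": rec.F1[:, 1],
        "f2x": rec.F2[:, 0], "f2y": rec.F2[:, 1],
    })


def write_trial_csv(rec: TrialRecord, path) -> None:
    trial_to_frame(rec).to_csv(path, index=False, float_format="%.9g")


def read_trial_csv(path, connected: bool | None = None) -> TrialRecord:
    """Read a raw trial CSV (extra columns, e.g. z components, ignored).

    Only position and force series are stored in the file; velocity and
    activation blocks of the reconstructed record are zero and should be
    re-derived by the smoothing pipeline.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV missing columns: {missing}")
    T = len(df)
    states = np.zeros((T, 22))
    states[:, 0:2] = df[["p1x", "p1y"]].to_numpy()
    states[:, 8:10] = df[["p2x", "p2y"]].to_numpy()
    F1 = df[["f1x", "f1y"]].to_numpy()
    F2 = df[["f2x", "f2y"]].to_numpy()
    dt = float(np.median(np.diff(df["t"].to_numpy()))) if T > 1 else 0.01
    if connected is None:
        connected = bool(np.any(F1 != 0.0))
    return TrialRecord(states=states, u1=np.zeros((T - 1, 2)),
                       u2=np.zeros((T - 1, 2)), F1=F1, F2=F2, dt=dt,
                       connected=connected)
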