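"""Synthetic inputs: protocols, model-generated sessions and parametric fixtures.

Two kinds of synthetic data are produced.  `generate_group_dataset`
runs the full learning model per dyad and writes raw trial CSVs plus
per-indicator matrices with one row per dyad and one column per trial —
the layout of the study-style indicator tables.  `make_fixture_trial`
builds *model-free* kinematic fixtures (minimum-jerk paths through the
via-points with a controllable lead/lag between the players) whose
indicator values are known by construction; these exercise the analysis
pipeline independently of the control model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .indicators import INDICATOR_NAMES, session_indicators, write_trial_csv
from .learning import ProtocolSpec, run_protocol
from .plant import GROUPS, DyadParams, Geometry, build_plant
from .records import TrialRecord


def make_protocol(group: str, seed: int = 0) -> ProtocolSpec:
    """Standard 13-epoch schedule (12 trials each): baseline, 10 training
    epochs with 2 seeded catch trials apiece, and 2 after-effect epochs."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    return ProtocolSpec(group=group, seed=seed)


# ---------------------------------------------------------------------------
# minimum-jerk fixtures


@dataclass
class FixtureSpec:
    """Parametric two-player trial with controllable leader-follower lag.

    ``lag_tau > 0`` puts player 2 *ahead* of player 1 by ``lag_tau``
    seconds along the common path (player 2 leads); negative values make
    player 2 the follower.  ``noise_std`` adds seeded Gaussian jitter to
    the sampled positions.
    """

    kind: str = "via_point_minimum_jerk"
    lag_tau: float = 0.0
    noise_std: float = 0.0
    duration: float = 2.0
    rate: float = 100.0
    seed: int = 0
    spring_k: float = 150.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be > 0")
        if self.kind not in ("via_point_minimum_jerk", "straight", "custom"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def _min_jerk(p0: np.ndarray, p1: np.ndarray, s: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk interpolation between rest states; s in [0, 1].

    Returns positions and the derivative with respect to s.
    """
    blend = 10 * s**3 - 15 * s**4 + 6 * s**5
    dblend = 30 * s**2 - 60 * s**3 + 30 * s**4
    d = (p1 - p0)[None, :]
    return p0[None, :] + blend[:, None] * d, dblend[:, None] * d


def _waypoint_path(waypoints: list[np.ndarray], fractions: list[float],
                   duration: float, t: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise minimum-jerk path through waypoints at given time fractions."""
    t = np.clip(t, 0.0, duration)
    pos = np.zeros((t.shape[0], 2))
    vel = np.zeros((t.shape[0], 2))
    bounds = np.array(fractions) * duration
    for i in range(len(waypoints) - 1):
        t0, t1 = bounds[i], bounds[i + 1]
        mask = (t >= t0) & (t <= t1) if i == len(waypoints) - 2 else (t >= t0) & (t < t1)
        if not np.any(mask):
            continue
        s = (t[mask] - t0) / (t1 - t0)
        p, dp = _min_jerk(waypoints[i], waypoints[i + 1], s)
        pos[mask] = p
        vel[mask] = dp / (t1 - t0)
    return pos, vel


def make_fixture_trial(spec: FixtureSpec,
                       geometry: Geometry | None = None) -> TrialRecord:
    """Generate a two-player kinematic fixture trial.

    The common path runs start -> VP1 -> VP2 -> target; both players
    therefore pass exactly through both via-points (MD to own via-point
    is 0 before noise).  Forces follow the spring law on the generated
    positions, so the leader-follower sign pattern of the interaction
    power is fixed by ``lag_tau``.
    """
    if geometry is None:
        geometry = Geometry()
    n = int(round(spec.duration * spec.rate))
    dt = 1.0 / spec.rate
    t = np.arange(n) * dt
    if spec.kind == "straight":
        waypoints = [geometry.start, geometry.target]
        fractions = [0.0, 1.0]
    else:
        waypoints = [geometry.start, geometry.vp1, geometry.vp2, geometry.target]
        fractions = [0.0, 0.35, 0.65, 1.0]
    p1, v1 = _waypoint_path(waypoints, fractions, spec.duration, t)
    p2, v2 = _waypoint_path(waypoints, fractions, spec.duration, t + spec.lag_tau)
    if spec.noise_std > 0:
        rng = np.random.default_rng(spec.seed)
        p1 = p1 + rng.standard_normal(p1.shape) * spec.noise_std
        p2 = p2 + rng.standard_normal(p2.shape) * spec.noise_std
    F1 = -spec.spring_k * (p1 - p2)
    states = np.zeros((n, 22))
    states[:, 0:2] = p1
    states[:, 2:4] = v1
    states[:, 8:10] = p2
    states[:, 10:12] = v2
    states[:, 16:18] = geometry.target
    states[:, 18:20] = geometry.vp1
    states[:, 20:22] = geometry.vp2
    return TrialRecord(states=states, u1=np.zeros((n - 1, 2)),
                       u2=np.zeros((n - 1, 2)), F1=F1, F2=-F1, dt=dt,
                       connected=spec.spring_k > 0,
                       meta={"fixture": asdict(spec)})


# ---------------------------------------------------------------------------
# full model-generated group datasets


def _config_digest(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def generate_group_dataset(group: str, out_dir, n_dyads: int = 5,
                           seed: int = 42,
                           params: DyadParams | None = None,
                           geometry: Geometry | None = None,
                           write_raw: bool = True) -> dict[str, pd.DataFrame]:
    """Simulate ``n_dyads`` full sessions of one group and write the dataset.

    Layout under ``out_dir``: ``dyad00/trial000.csv`` ... raw trials
    (plus a JSON sidecar per dyad with seeds, units and a config
    digest), and one ``<indicator>_<group>.csv`` matrix per indicator
    with ``n_dyads`` rows and one column per trial.  Returns the
    indicator matrices keyed by indicator name.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = DyadParams()
    if geometry is None:
        geometry = Geometry()
    plant = build_plant(params, geometry)
    digest = _config_digest({"group": group, "seed": seed, "n_dyads": n_dyads,
                             "params": asdict(params), "geometry": asdict(geometry)})
    dyad_seeds = np.random.SeedSequence(seed).generate_state(n_dyads) % (2**31)
    matrices = {name: [] for name in INDICATOR_NAMES}
    for d in range(n_dyads):
        spec = make_protocol(group, seed=int(dyad_seeds[d]))
        session = run_protocol(spec, plant, seed=int(dyad_seeds[d]))
        table = session_indicators(session.records, geometry.vp1, geometry.vp2)
        for name in INDICATOR_NAMES:
            matrices[name].append(table[name].to_numpy())
        if write_raw:
            ddir = out_dir / f"dyad{d:02d}"
            ddir.mkdir(exist_ok=True)
            for rec in session.records:
                write_trial_csv(rec, ddir / f"trial{rec.trial_index:03d}.csv")
            sidecar = {
                "group": group, "dyad": d, "seed": int(dyad_seeds[d]),
                "units": {"position": "m", "force": "N", "t": "s"},
                "sample_rate_hz": 1.0 / plant.dt,
                "config_digest": digest,
            }
            (ddir / "session.json").write_text(json.dumps(sidecar, indent=1))
    out = {}
    for name in INDICATOR_NAMES:
        M = pd.DataFrame(np.vstack(matrices[name]))
        M.to_csv(out_dir / f"{name}_{group}.csv", index=False, header=False,
                 float_format="%.9g")
        out[name] = M
    (out_dir / "dataset.json").write_text(json.dumps(
        {"group": group, "seed": seed, "n_dyads": n_dyads,
         "config_digest": digest}, indent=1))
    return out
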