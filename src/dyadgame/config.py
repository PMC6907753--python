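"""Default configuration, YAML round-trip and object construction.

All physically meaningful defaults live here in one unit-annotated
mapping so that a whole simulation is reproducible from a single YAML
file.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .observer import DEFAULT_A_U, DEFAULT_SIGMA_EPS, DEFAULT_U_PRIOR_VAR
from .plant import DEFAULT_NOISE_PROFILES, DyadParams, Geometry, build_plant
from .tasks import DEFAULT_VIA_FRACTION, DEFAULT_WEIGHTS, build_cost

DEFAULT_CONFIG = {
    "plant": {
        "mass_per_player_kg": 1.0,
        "spring_k_N_per_m": 150.0,
        "damping_N_s_per_m": 12.0,
        "dt_s": 0.01,
        "activation_tau_s": [0.04, 0.04],
        "motor_noise_std_N": 0.3,
        "horizon_T_steps": 200,
    },
    "geometry_m": {
        "start": [-0.05, 0.0],
        "target": [0.05, 0.0],
        "vp1": [-0.03, -0.02],
        "vp2": [0.03, 0.02],
    },
    "cost": {
        "weights": dict(DEFAULT_WEIGHTS),
        "via_fraction": {str(k): v for k, v in DEFAULT_VIA_FRACTION.items()},
    },
    "sensory_noise": copy.deepcopy(DEFAULT_NOISE_PROFILES),
    "observer": {
        "a_u": DEFAULT_A_U,
        "sigma_eps_N": DEFAULT_SIGMA_EPS,
        "u_prior_var_N2": DEFAULT_U_PRIOR_VAR,
        "p0_scale": 1e-6,
        "process_noise_floor": 1e-3,
    },
    "learning": {
        "estimate_smoothing": 0.85,
    },
    "verification": {
        "nash_rel_tol": 1e-6,
        "n_perturb": 200,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}

    def merge(base: dict, over: dict) -> dict:
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v)
            else:
                base[k] = v
        return base

    return merge(cfg, user)


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def plant_from_config(cfg: dict):
    p = cfg["plant"]
    params = DyadParams(
        mass_per_player=p["mass_per_player_kg"],
        spring_k=p["spring_k_N_per_m"],
        damping=p["damping_N_s_per_m"],
        dt=p["dt_s"],
        activation_tau=tuple(p["activation_tau_s"]),
        motor_noise_std=p["motor_noise_std_N"],
        horizon_T=p["horizon_T_steps"],
    )
    g = cfg["geometry_m"]
    geometry = Geometry(start=g["start"], target=g["target"],
                        vp1=g["vp1"], vp2=g["vp2"])
    return build_plant(params, geometry)


def costs_from_config(cfg: dict, plant):
    weights = cfg["cost"]["weights"]
    T = plant.horizon_T
    frac = cfg["cost"]["via_fraction"]
    return tuple(
        build_cost(i, plant, weights=weights,
                   via_time=int(round(float(frac[str(i)]) * T)))
        for i in (1, 2))
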