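"""Estimating the partner's motor command from one's own senses.

Each player runs a Kalman observer on an augmented plant whose extra
state is the partner's command, modelled as a slowly varying input.
This script makes player 2 produce a smooth time-varying force while
player 1 estimates it through the sensory channels of each experimental
group: haptic only (H), visuo-haptic (VH), or partner-visible (PV).
More information about the partner gives a smaller tracking error.
"""

import numpy as np

import dyadgame as dg
from dyadgame.observer import (KalmanObserver, initial_observer_state,
                               kalman_gain_schedule, smoother_gain_schedule)

plant = dg.build_plant(dg.DyadParams())
T = plant.horizon_T


def partner_command(t):
    return np.array([2.0 * np.sin(2 * np.pi * 0.75 * t),
                     1.0 * np.sin(2 * np.pi * 1.5 * t)])


for group in ("H", "VH", "PV"):
    sens = dg.build_sensory_model(group, plant, player_id=1)
    rmses = []
    for seed in range(5):
        obs = KalmanObserver(plant, sens)
        K, Pp, Pm = kalman_gain_schedule(obs.aug, sens,
                                         initial_observer_state(plant).P, T,
                                         return_priors=True)
        obs.K_seq = K
        obs.G_seq = smoother_gain_schedule(obs.aug, Pp, Pm)
        obs.record_history = True
        rng = np.random.default_rng(seed)
        x = plant.initial_state()
        truth = []
        for t in range(T - 1):
            u2 = partner_command(t * plant.dt)
            x = dg.step_dynamics(plant, x, np.zeros(2), u2, rng=rng)
            obs.step(obs.measure(x, rng=rng), np.zeros(2))
            truth.append(u2)
        est = obs.smoothed_partner_inputs()
        err = np.linalg.norm(est[50:] - np.array(truth)[50:], axis=1)
        rmses.append(np.sqrt(np.mean(err**2)))
    print(f"{group:>3}: partner-command tracking RMSE = "
          f"{np.mean(rmses):.3f} N (5 seeds)")

# The RMSE falls from H to VH to PV: the displayed force vector (VH) and
# especially the partner's visible cursor (PV) sharpen the estimate of
# what the partner is doing — the information gradient the three
# experimental groups were designed to create.
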