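import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dyadgame as dg

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plant():
    return dg.build_plant(dg.DyadParams())


@pytest.fixture(scope="session")
def costs(plant):
    return dg.build_cost(1, plant), dg.build_cost(2, plant)


@pytest.fixture(scope="session")
def nash_policies(plant, costs):
    return dg.solve_nash(plant, *costs)


@pytest.fixture(scope="session")
def nash_record(plant, nash_policies):
    return dg.simulate_closed_loop(plant, nash_policies)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _estimation_run(plant, group, seed, u_fun, scale=1.0, motor=True,
                    smoothed=False):
    """Closed-loop partner estimation probe: player 1 at rest estimates a
    prescribed player-2 command under a group's sensory model."""
    from dyadgame.observer import (KalmanObserver, initial_observer_state,
                                   kalman_gain_schedule, smoother_gain_schedule)
    prof = {k: v * scale for k, v in
            dg.plant.DEFAULT_NOISE_PROFILES[group].items()}
    sens = dg.build_sensory_model(group, plant, player_id=1, noise_profile=prof)
    ob = KalmanObserver(plant, sens)
    K, Pp, Pm = kalman_gain_schedule(ob.aug, sens,
                                     initial_observer_state(plant).P,
                                     plant.horizon_T, return_priors=True)
    ob.K_seq = K
    if smoothed:
        ob.G_seq = smoother_gain_schedule(ob.aug, Pp, Pm)
        ob.record_history = True
    gen = np.random.default_rng(seed)
    x = plant.initial_state()
    est, tru = [], []
    for t in range(plant.horizon_T - 1):
        u2 = u_fun(t * plant.dt)
        x = dg.step_dynamics(plant, x, np.zeros(2), u2,
                             rng=gen if motor else None)
        ob.step(ob.measure(x, rng=gen), np.zeros(2))
        est.append(ob.partner_input_estimate())
        tru.append(u2)
    est = ob.smoothed_partner_inputs() if smoothed else np.array(est)
    return est, np.array(tru)


@pytest.fixture(scope="session")
def estimation_run():
    return _estimation_run
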