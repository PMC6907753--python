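import numpy as np
import pytest

import dyadgame as dg
from dyadgame.control import AffineLQR, PolicySet, solve_open_loop_nash
from dyadgame.learning import merge_policies
from dyadgame.plant import STATE_DIM, DyadParams, Geometry
from dyadgame.tasks import build_cost, evaluate_cost, zero_cost


def textbook_lqr(A, B, Q_seq, R, T):
    """Independent finite-horizon LQR oracle (plain Riccati recursion)."""
    P = Q_seq[T].copy()
    gains = []
    for t in range(T - 1, 0, -1):
        G = R + B.T @ P @ B
        L = np.linalg.solve(G, B.T @ P @ A)
        P = Q_seq[t] + A.T @ P @ (A - B @ L)
        gains.append(L)
    return np.array(gains[::-1])


class TestSolveNash:
    def test_reduces_to_lqr_when_partner_removed(self, plant):
        """With cost2 = 0 and B2 = 0 the game is a one-player LQR problem."""
        import dataclasses
        T = plant.horizon_T
        reduced = dataclasses.replace(plant, B2=np.zeros_like(plant.B2))
        c1 = build_cost(1, reduced)
        c2 = zero_cost(2, T)
        pol = dg.solve_nash(reduced, c1, c2)
        oracle = textbook_lqr(reduced.A, reduced.B1, c1.Q_seq, c1.R, T)
        np.testing.assert_allclose(pol.L1_seq, oracle, atol=1e-8)

    def test_symmetric_game_symmetric_gains(self):
        """A fully mirror-symmetric game yields mirror-symmetric policies."""
        geom = Geometry(start=[-0.05, 0.0], target=[0.05, 0.0],
                        vp1=[-0.02, -0.02], vp2=[0.02, 0.02])
        plant = dg.build_plant(DyadParams(horizon_T=100), geom)
        T = 100
        c1 = build_cost(1, plant, via_time=35)
        c2 = build_cost(2, plant, via_time=65)
        # mirror both costs onto the middle step for exact symmetry
        c1 = build_cost(1, plant, via_time=50)
        c2 = build_cost(2, plant, via_time=50)
        pol = dg.solve_nash(plant, c1, c2)
        # swap player blocks and vp blocks, negate spatial axes
        M = np.zeros((STATE_DIM, STATE_DIM))
        M[0:8, 8:16] = -np.eye(8)
        M[8:16, 0:8] = -np.eye(8)
        M[16:18, 16:18] = -np.eye(2)
        M[18:20, 20:22] = -np.eye(2)
        M[20:22, 18:20] = -np.eye(2)
        for t in (0, 49, 98):
            np.testing.assert_allclose(pol.L2_seq[t], -pol.L1_seq[t] @ M,
                                       atol=1e-8)

    def test_no_unilateral_improvement(self, plant, costs, nash_policies):
        rep = dg.verify_nash(plant, *costs, nash_policies, n_perturb=60, seed=0)
        J1 = rep["J1"]
        assert rep["max_improvement"][1] <= 1e-6
        assert rep["max_improvement"][2] <= 1e-6
        assert J1 > 0

    def test_verify_nash_detects_corruption(self, plant, costs, nash_policies):
        bad = PolicySet(L1_seq=nash_policies.L1_seq * 1.3,
                        L2_seq=nash_policies.L2_seq, scenario="bad")
        rep = dg.verify_nash(plant, *costs, bad, n_perturb=60, seed=1)
        assert rep["max_improvement"][1] > 1e-6

    def test_verify_nash_empty_report(self, plant, costs, nash_policies):
        rep = dg.verify_nash(plant, *costs, nash_policies, n_perturb=0)
        assert rep["n_perturb"] == 0
        assert rep["max_improvement"] == {1: 0.0, 2: 0.0}

    def test_nash_rollout_passes_both_via_points(self, plant, nash_record):
        g = plant.geometry
        for player, own_vp in ((1, g.vp1), (2, g.vp2)):
            p = nash_record.positions(player)
            for vp in (g.vp1, g.vp2):
                assert np.min(np.linalg.norm(p - vp, axis=1)) < 0.005
            assert np.linalg.norm(p[-1] - g.target) < 0.005


class TestOneDimensionalToyOracle:
    def test_matches_open_loop_grid_search(self):
        """2-step scalar game: solve_nash against brute-force enumeration.

        Players control scalar accelerations over a coarse action grid;
        the exhaustive grid search finds the open-loop action-pair Nash
        fixed point, which for this single-stage-relevant horizon
        coincides with the feedback solution at the grid resolution.
        """
        # scalar "positions" via the x-axis only; tiny horizon
        params = DyadParams(horizon_T=3, spring_k=50.0, damping=2.0)
        plant = dg.build_plant(params)
        T = 3
        c1 = build_cost(1, plant, via_time=1,
                        weights={"w_vp": 10.0, "w_target": 100.0, "w_stop": 0.0,
                                 "w_force": 5.0, "w_effort": 0.01})
        c2 = build_cost(2, plant, via_time=1,
                        weights={"w_vp": 10.0, "w_target": 100.0, "w_stop": 0.0,
                                 "w_force": 5.0, "w_effort": 0.01})
        pol = dg.solve_nash(plant, c1, c2)
        x0 = plant.initial_state()

        def rollout(u1s, u2s):
            x = x0.copy()
            states = [x]
            for t in range(T - 1):
                x = plant.A @ x + plant.B1 @ u1s[t] + plant.B2 @ u2s[t]
                states.append(x)
            return np.array(states)

        # closed-loop actions of the Riccati solution
        x = x0.copy()
        u1_cl, u2_cl = [], []
        for t in range(1, T):
            u1_cl.append(pol.control(1, t, x))
            u2_cl.append(pol.control(2, t, x))
            x = plant.A @ x + plant.B1 @ u1_cl[-1] + plant.B2 @ u2_cl[-1]
        u1_cl, u2_cl = np.array(u1_cl), np.array(u2_cl)

        # brute-force best-response iteration on a fine grid around it
        grid = np.linspace(-2.0, 2.0, 81)

        def best_response(other_us, B_own, B_other, spec):
            best, best_cost = None, np.inf
            for a0 in grid:
                for a1 in grid:
                    us = np.array([[a0, 0.0], [a1, 0.0]])
                    if B_own is plant.B1:
                        states = rollout(us, other_us)
                        J = evaluate_cost(states, us, spec)
                    else:
                        states = rollout(other_us, us)
                        J = evaluate_cost(states, us, spec)
                    if J < best_cost:
                        best, best_cost = us, J
            return best

        u1 = np.zeros((2, 2))
        u2 = np.zeros((2, 2))
        for _ in range(6):
            u1 = best_response(u2, plant.B1, plant.B2, c1)
            u2 = best_response(u1, plant.B2, plant.B1, c2)
        step = grid[1] - grid[0]
        np.testing.assert_allclose(u1[:, 0], u1_cl[:, 0], atol=step)
        np.testing.assert_allclose(u2[:, 0], u2_cl[:, 0], atol=step)


class TestNoPartner:
    def test_equals_lqr_oracle(self, plant, costs):
        pol = dg.solve_no_partner(plant, costs[0])
        oracle = textbook_lqr(plant.A, plant.B1, costs[0].Q_seq,
                              costs[0].R, plant.horizon_T)
        np.testing.assert_allclose(pol.L1_seq, oracle, atol=1e-8)
        assert pol.L2_seq is None

    def test_coincides_with_nash_in_decoupled_game(self):
        plant = dg.build_plant(DyadParams(spring_k=0.0, horizon_T=80))
        W = {"w_force": 0.0}
        c1 = build_cost(1, plant, weights=W)
        c2 = build_cost(2, plant, weights=W)
        nash = dg.solve_nash(plant, c1, c2)
        np1 = dg.solve_no_partner(plant, c1)
        np2 = dg.solve_no_partner(plant, c2)
        np.testing.assert_allclose(nash.L1_seq, np1.L1_seq, atol=1e-9)
        np.testing.assert_allclose(nash.L2_seq, np2.L2_seq, atol=1e-9)

    def test_role_alternation_sign_pattern(self, plant, costs):
        """No-partner play: each player leads at the own via-point and is
        pulled (follows) at the partner's — alternating leader/follower
        roles within the movement."""
        from dyadgame.indicators import trial_indicators
        pol = merge_policies(dg.solve_no_partner(plant, costs[0]),
                             dg.solve_no_partner(plant, costs[1]))
        rec = dg.simulate_closed_loop(plant, pol)
        g = plant.geometry
        row = trial_indicators(rec, g.vp1, g.vp2)
        assert row.LI22 < 0 < row.LI12   # vp2: player 2 leads, player 1 is pulled
        assert row.LI11 < 0               # vp1: player 1 leads
        assert row.dLI1 > 0 and row.dLI2 > 0  # role specialization at both vps

    def test_no_partner_roles_stronger_than_nash(self, plant, costs,
                                                 nash_policies, nash_record):
        """Peak coupling force and role indices exceed the Nash ones."""
        from dyadgame.indicators import trial_indicators
        pol = merge_policies(dg.solve_no_partner(plant, costs[0]),
                             dg.solve_no_partner(plant, costs[1]))
        from dyadgame.indicators import compute_power
        rec_np = dg.simulate_closed_loop(plant, pol)
        g = plant.geometry
        row_np = trial_indicators(rec_np, g.vp1, g.vp2)
        row_nash = trial_indicators(nash_record, g.vp1, g.vp2)
        assert np.abs(rec_np.F1).max() > np.abs(nash_record.F1).max()
        for player in (1, 2):
            peak_np = np.abs(compute_power(
                rec_np.F1 if player == 1 else rec_np.F2,
                rec_np.velocities(player))).max()
            peak_nash = np.abs(compute_power(
                nash_record.F1 if player == 1 else nash_record.F2,
                nash_record.velocities(player))).max()
            assert peak_np > peak_nash
        assert row_np.IF > row_nash.IF


class TestSimulateClosedLoop:
    def test_noiseless_rollout_bit_identical(self, plant, nash_policies):
        a = dg.simulate_closed_loop(plant, nash_policies)
        b = dg.simulate_closed_loop(plant, nash_policies)
        np.testing.assert_array_equal(a.states, b.states)

    def test_seeded_noise_reproducible(self, plant, nash_policies):
        a = dg.simulate_closed_loop(plant, nash_policies, seed=9, with_noise=True)
        b = dg.simulate_closed_loop(plant, nash_policies, seed=9, with_noise=True)
        np.testing.assert_array_equal(a.states, b.states)
        c = dg.simulate_closed_loop(plant, nash_policies, seed=10, with_noise=True)
        assert np.abs(a.states - c.states).max() > 0

    def test_unconnected_players_visit_only_own_via_point(self):
        """k = 0 and w_force = 0: solo reaching through the own via-point,
        staying far from the partner's."""
        plant = dg.build_plant(DyadParams(spring_k=0.0))
        W = {"w_force": 0.0}
        c1 = build_cost(1, plant, weights=W)
        c2 = build_cost(2, plant, weights=W)
        pol = merge_policies(dg.solve_no_partner(plant, c1),
                             dg.solve_no_partner(plant, c2))
        rec = dg.simulate_closed_loop(plant, pol)
        g = plant.geometry
        p1, p2 = rec.positions(1), rec.positions(2)
        assert np.min(np.linalg.norm(p1 - g.vp1, axis=1)) < 0.005
        assert np.min(np.linalg.norm(p2 - g.vp2, axis=1)) < 0.005
        assert np.min(np.linalg.norm(p1 - g.vp2, axis=1)) > 0.015
        assert np.min(np.linalg.norm(p2 - g.vp1, axis=1)) > 0.015

    def test_divergence_reported_with_step(self, plant, nash_policies):
        bad = PolicySet(L1_seq=-5.0 * nash_policies.L1_seq,
                        L2_seq=nash_policies.L2_seq)
        with pytest.raises(FloatingPointError, match="step"):
            dg.simulate_closed_loop(plant, bad)


class TestAffineLQR:
    def test_feedforward_matches_brute_force_qp(self):
        """Affine best response against a drift equals the exact QP optimum."""
        params = DyadParams(horizon_T=30)
        plant = dg.build_plant(params)
        T = 30
        c1 = build_cost(1, plant, via_time=10)
        rng = np.random.default_rng(2)
        u2_seq = rng.standard_normal((T - 1, 2)) * 0.5
        c_seq = np.zeros((T, STATE_DIM))
        c_seq[1:] = u2_seq @ plant.B2.T
        lqr = AffineLQR(plant.A, plant.B1, c1.Q_seq, c1.R, T)
        f_seq = lqr.feedforward(c_seq)

        # closed-loop actions
        x = plant.initial_state()
        us, xs = [], [x]
        for t in range(1, T):
            u = -lqr.L_seq[t - 1] @ x + f_seq[t - 1]
            x = plant.A @ x + plant.B1 @ u + plant.B2 @ u2_seq[t - 1]
            us.append(u)
            xs.append(x)
        J_pol = evaluate_cost(np.array(xs[:T]), np.array(us), c1)

        # brute-force QP over open-loop u1
        n, N = STATE_DIM, (T - 1) * 2
        Phi = np.zeros((T, n, N))
        const = np.zeros((T, n))
        const[0] = plant.initial_state()
        for t in range(1, T):
            const[t] = plant.A @ const[t - 1] + plant.B2 @ u2_seq[t - 1]
            Phi[t] = plant.A @ Phi[t - 1]
            Phi[t][:, 2 * (t - 1):2 * t] += plant.B1
        H = np.zeros((N, N))
        grad = np.zeros(N)
        for t in range(1, T + 1):
            Q = c1.Q_seq[t]
            Pm, cv = Phi[t - 1], const[t - 1]
            H += Pm.T @ Q @ Pm
            grad += Pm.T @ Q @ cv
        for t in range(T - 1):
            H[2 * t:2 * t + 2, 2 * t:2 * t + 2] += c1.R
        u_opt = np.linalg.solve(H, -grad).reshape(T - 1, 2)
        xs_opt = np.array([const[t] + Phi[t] @ u_opt.ravel() for t in range(T)])
        J_opt = evaluate_cost(xs_opt, u_opt, c1)
        assert J_pol == pytest.approx(J_opt, rel=1e-10)

    def test_open_loop_nash_is_mutual_best_response(self, plant, costs):
        sol = solve_open_loop_nash(plant, *costs)
        assert sol["converged"]
        # re-solving either player's best response reproduces their sequence
        T = costs[0].T
        lqr1 = AffineLQR(plant.A, plant.B1, costs[0].Q_seq, costs[0].R, T)
        c_seq = np.zeros((T, STATE_DIM))
        c_seq[1:] = sol["u2_seq"] @ plant.B2.T
        f = lqr1.feedforward(c_seq)
        x = plant.initial_state()
        for t in range(1, T):
            u = -lqr1.L_seq[t - 1] @ x + f[t - 1]
            np.testing.assert_allclose(u, sol["u1_seq"][t - 1], atol=1e-8)
            x = plant.A @ x + plant.B1 @ u + plant.B2 @ sol["u2_seq"][t - 1]
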