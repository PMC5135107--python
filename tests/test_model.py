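"""Plant matrices, LQR solution and closed-loop simulation behaviour."""

import numpy as np
import pytest

from dyadreach.errors import ParameterError
from dyadreach.model import (
    MotionPlan,
    PlantParams,
    WristState,
    build_system_matrices,
    constrained_pushpull_state,
    init_pushpull_state,
    simulate_dyad,
    simulate_solo,
    solve_lqr_gain,
    torsional_to_linear_stiffness,
)


def value_iteration_gain(A, B, Q, R, horizon=10**5):
    """Independent finite-horizon dynamic-programming oracle for the LQR gain."""
    S = Q.copy()
    for _ in range(horizon):
        SB = S @ B
        gain_den = R + (B.T @ SB).item()
        S = Q + A.T @ S @ A - (A.T @ SB) @ (SB.T @ A) / gain_den
        S = 0.5 * (S + S.T)
    return (B.T @ S @ A) / (R + (B.T @ S @ B).item())


class TestSystemMatrices:
    def test_muscle_filter_entries(self, plant):
        sys = build_system_matrices(plant, coupled=False)
        assert sys.A[2, 2] == pytest.approx(0.75)
        assert sys.A[3, 3] == pytest.approx(0.75)
        assert sys.B[3, 0] == pytest.approx(0.25)
        assert sys.A[0, 1] == plant.dt
        assert sys.A[1, 2] == pytest.approx(plant.dt / plant.inertia)

    def test_decoupled_connection_is_zero(self, plant):
        sys = build_system_matrices(plant, coupled=False)
        assert np.all(sys.C == 0)

    def test_coupling_entries(self, plant):
        sys = build_system_matrices(plant, coupled=True)
        expected = np.zeros((4, 4))
        expected[1, 0] = 0.04   # K dt / I
        expected[1, 1] = 0.005  # D dt / I
        np.testing.assert_allclose(sys.C, expected)

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"inertia": 0.0}, "inertia"),
            ({"dt": -0.01}, "dt"),
            ({"tau_u": 0.005}, "tau_u"),
            ({"stiffness": -1.0}, "stiffness"),
            ({"damping": -0.1}, "damping"),
        ],
    )
    def test_invalid_plant_names_field(self, kwargs, field):
        with pytest.raises(ParameterError, match=field):
            PlantParams(**kwargs)


class TestLqrGain:
    def test_zero_state_cost_gives_zero_gain(self, plant):
        sys = build_system_matrices(plant, coupled=False)
        with pytest.warns(UserWarning, match="no regulation"):
            gain = solve_lqr_gain(sys, MotionPlan(0.0, 0.0))
        np.testing.assert_array_equal(gain.L, np.zeros((1, 4)))

    def test_fixed_point_residual(self, plant):
        sys = build_system_matrices(plant, coupled=False)
        gain = solve_lqr_gain(sys, MotionPlan(2.0, 0.1))
        A, B = sys.A, sys.B
        S = gain.S
        SB = S @ B
        rhs = MotionPlan(2.0, 0.1).Q + A.T @ (S - SB @ SB.T / (0.5 + (B.T @ SB).item())) @ A
        assert np.max(np.abs(S - rhs)) < 1e-8

    def test_matches_value_iteration_oracle(self, plant):
        sys = build_system_matrices(plant, coupled=False)
        plan = MotionPlan(2.0, 0.1)
        gain = solve_lqr_gain(sys, plan)
        L_oracle = value_iteration_gain(sys.A, sys.B, plan.Q, plan.r, horizon=10**5)
        np.testing.assert_allclose(gain.L, L_oracle, atol=1e-6)

    def test_matches_scipy_dare(self, plant):
        from scipy.linalg import solve_discrete_are

        sys = build_system_matrices(plant, coupled=False)
        plan = MotionPlan(3.0, 0.25)
        gain = solve_lqr_gain(sys, plan)
        S = solve_discrete_are(sys.A, sys.B, plan.Q, np.array([[plan.r]]))
        np.testing.assert_allclose(gain.S, S, atol=1e-7)

    def test_closed_loop_stable_when_position_weighted(self, plant, rng):
        sys = build_system_matrices(plant, coupled=False)
        for _ in range(5):
            plan = MotionPlan(float(rng.uniform(0.5, 20)), float(rng.uniform(0, 2)))
            gain = solve_lqr_gain(sys, plan)
            eig = np.linalg.eigvals(sys.A - sys.B @ gain.L)
            assert np.max(np.abs(eig)) < 1.0

    def test_gain_invariant_to_common_cost_scaling(self, plant):
        sys = build_system_matrices(plant, coupled=False)
        L1 = solve_lqr_gain(sys, MotionPlan(2.0, 0.1, r=0.5)).L
        L2 = solve_lqr_gain(sys, MotionPlan(2.0 * 7.0, 0.1 * 7.0, r=0.5 * 7.0)).L
        np.testing.assert_allclose(L1, L2, atol=1e-7)


class TestSimulateSolo:
    def test_target_is_equilibrium(self, plant):
        plan = MotionPlan(2.0, 0.1)
        x0 = WristState(plan.theta_target, 0.0, 0.0, 0.0)
        trace = simulate_solo(plan, plant, x0, 1.0)
        np.testing.assert_allclose(trace.angle(), plan.theta_target, atol=1e-10)

    def test_position_priority_overshoots(self, plant, position_priority_plan):
        trace = simulate_solo(
            position_priority_plan, plant, WristState(-10, 0, 0, 0), 3.0
        )
        assert trace.angle().max() > position_priority_plan.theta_target + 0.3
        assert trace.angle()[-1] == pytest.approx(30.0, abs=0.1)

    def test_velocity_priority_approaches_monotonically(self, plant):
        plan = MotionPlan(0.5, 0.5)
        trace = simulate_solo(plan, plant, WristState(-10, 0, 0, 0), 3.0)
        assert trace.angle().max() <= plan.theta_target + 1e-6

    def test_duration_must_be_multiple_of_dt(self, plant):
        with pytest.raises(ParameterError, match="duration"):
            simulate_solo(MotionPlan(2, 0.1), plant, WristState(-10, 0, 0, 0), 1.005)

    def test_interaction_torque_zero_for_solo(self, plant):
        trace = simulate_solo(MotionPlan(2, 0.1), plant, WristState(-10, 0, 0, 0), 1.0)
        np.testing.assert_array_equal(trace.interaction_torque, 0.0)


class TestSimulateDyad:
    def test_identical_partners_exchange_no_torque(self, plant, rest_pair):
        plan = MotionPlan(3.0, 0.2)
        trace = simulate_dyad(plan, plan, plant, rest_pair, 2.0)
        np.testing.assert_array_equal(trace.interaction_torque, 0.0)

    def test_newtons_third_law(self, plant, rest_pair,
                               position_priority_plan, velocity_priority_plan):
        trace = simulate_dyad(
            position_priority_plan, velocity_priority_plan, plant, rest_pair, 2.0
        )
        s1, s2 = trace.states
        on_1 = plant.stiffness * (s2[:, 0] - s1[:, 0]) + plant.damping * (s2[:, 1] - s1[:, 1])
        on_2 = plant.stiffness * (s1[:, 0] - s2[:, 0]) + plant.damping * (s1[:, 1] - s2[:, 1])
        np.testing.assert_array_equal(on_1, -on_2)
        np.testing.assert_array_equal(trace.interaction_torque, on_1)

    def test_weak_coupling_approaches_solo_limit(self, rest_pair):
        p1, p2 = MotionPlan(5.0, 0.1), MotionPlan(1.0, 0.4)
        for eps, tol in [(1e-3, 0.5), (1e-6, 1e-3)]:
            plant = PlantParams(stiffness=0.4 * eps, damping=0.05 * eps)
            trace = simulate_dyad(p1, p2, plant, rest_pair, 2.0)
            solo1 = simulate_solo(p1, plant, rest_pair[0], 2.0)
            solo2 = simulate_solo(p2, plant, rest_pair[1], 2.0)
            err = max(
                np.abs(trace.angle(0) - solo1.angle()).max(),
                np.abs(trace.angle(1) - solo2.angle()).max(),
            )
            assert err < tol

    def test_torque_decays_without_hold_rule(
        self, plant, rest_pair, position_priority_plan, velocity_priority_plan
    ):
        trace = simulate_dyad(
            position_priority_plan, velocity_priority_plan, plant, rest_pair, 3.0,
            hold_rule=False,
        )
        tau = np.abs(trace.interaction_torque)
        assert tau.max() > 1.0
        assert tau[-1] < 0.05 * tau.max()

    def test_hold_rule_freezes_biased_endpoints(
        self, plant, rest_pair, position_priority_plan, velocity_priority_plan
    ):
        trace = simulate_dyad(
            position_priority_plan, velocity_priority_plan, plant, rest_pair, 3.0,
            hold_rule=True, hold_target=30.0,
        )
        assert trace.hold_switch_index is not None
        assert trace.angle(0)[-1] > 30.0      # position-priority partner overshoots
        assert trace.angle(1)[-1] < 30.0      # velocity-priority partner undershoots
        tau = trace.interaction_torque
        assert abs(tau[-1]) > 0.05            # sustained terminal torque
        assert abs(tau[-1] - tau[-30]) < 1e-3  # and it is constant


class TestPushPullState:
    def test_unloaded_equilibrium(self, plant):
        plan = MotionPlan(2.0, 0.1)
        s1, s2 = init_pushpull_state(plan, plan, plant, theta0=-10.0, tau0=0.0)
        for s in (s1, s2):
            assert s.angle == pytest.approx(-10.0, abs=1e-6)
            assert s.torque == pytest.approx(0.0, abs=1e-6)

    def test_settled_state_matches_linear_fixed_point(self, plant):
        """The settled state solves the coupled linear equilibrium directly."""
        from dyadreach.model import build_system_matrices, gain_for

        plan = MotionPlan(2.0, 0.1)
        tau0 = 0.7
        with pytest.warns(UserWarning, match="torque"):
            s1, s2 = init_pushpull_state(plan, plan, plant, -10.0, tau0)
        sys = build_system_matrices(plant, coupled=True)
        L = gain_for(plan, plant)
        A, B, C = sys.A, sys.B.ravel(), sys.C
        t1 = np.array([-10.0, 0, tau0, 0])
        t2 = np.array([-10.0, 0, -tau0, 0])
        # fixed point of the 8-dim closed loop: x = A x - B L (x - t) + C (xp - x)
        eye = np.eye(4)
        M = np.block(
            [
                [A - np.outer(B, L) - C - eye, C],
                [C, A - np.outer(B, L) - C - eye],
            ]
        )
        rhs = -np.concatenate([np.outer(B, L) @ t1, np.outer(B, L) @ t2])
        x_star = np.linalg.solve(M, rhs)
        np.testing.assert_allclose(s1.to_array(), x_star[:4], atol=1e-6)
        np.testing.assert_allclose(s2.to_array(), x_star[4:], atol=1e-6)

    def test_constrained_equilibrium_holds_exact_torque(self, plant):
        s1, s2 = constrained_pushpull_state(plant, -10.0, 0.7)
        assert s1.torque == 0.7 and s2.torque == -0.7
        # spring transmits exactly the held torque; each wrist's net torque vanishes
        spring_on_1 = plant.stiffness * (s2.angle - s1.angle)
        assert spring_on_1 == pytest.approx(-0.7)
        assert 0.5 * (s1.angle + s2.angle) == pytest.approx(-10.0)

    def test_constrained_state_needs_coupling(self):
        with pytest.raises(ParameterError, match="stiffness"):
            constrained_pushpull_state(PlantParams(stiffness=0.0), -10.0, 0.7)


def test_torsional_to_linear_stiffness_apparatus_value():
    assert torsional_to_linear_stiffness(23.0, 0.1) == pytest.approx(2300.0)
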