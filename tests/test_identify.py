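"""Fit metric, candidate enumeration and the lattice plan search."""

import numpy as np
import pytest

from dyadreach.errors import DegenerateDataError, ShapeError
from dyadreach.identify import (
    BlockStatistics,
    IdentifiedPlan,
    MotionPlanIdentifier,
    PlanSearchConfig,
    SimSettings,
    compare_plans,
    fit_metric,
    floor_variances,
    neighbor_permutations,
    noiseless_block_statistics,
    sample_lattice_plans,
    tree_search_identify,
)
from dyadreach.model import MotionPlan, PlantParams, SimulationTrace

STEP = np.array([1.0, 0.05, 1.0, 1.0, 0.05, 1.0])


def _flat_trace(n=121, duration=1.2, angle=0.0, torque=0.0):
    """Trace of a dyad frozen at a constant angle with constant torque."""
    plant = PlantParams()
    time = np.linspace(0, duration, n)
    states = np.zeros((n, 4))
    states[:, 0] = angle
    return SimulationTrace(
        time=time,
        states=(states, states.copy()),
        commands=(np.zeros(n - 1), np.zeros(n - 1)),
        interaction_torque=np.full(n, -torque),  # data convention flips sign
        plant=plant,
    )


class TestFitMetric:
    def test_perfect_fit_is_zero(self):
        trace = _flat_trace(angle=5.0, torque=0.3)
        stats = BlockStatistics(
            mean_angle=np.full(256, 5.0),
            mean_torque=np.full(256, 0.3),
            var_angle=np.ones(256),
            var_torque=np.ones(256),
        )
        assert fit_metric(trace, stats) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        """L=2, angle residuals [0, 2], unit variances -> M = (1/4) * 4 = 1."""
        trace = _flat_trace(angle=0.0, torque=0.0)
        stats = BlockStatistics(
            mean_angle=np.array([0.0, 2.0]),
            mean_torque=np.zeros(2),
            var_angle=np.ones(2),
            var_torque=np.ones(2),
        )
        assert fit_metric(trace, stats) == pytest.approx(1.0)

    def test_doubling_variances_halves_metric(self):
        trace = _flat_trace()
        stats1 = BlockStatistics(
            mean_angle=np.linspace(0, 3, 256),
            mean_torque=np.linspace(0, 1, 256),
            var_angle=np.ones(256),
            var_torque=np.ones(256),
        )
        stats2 = BlockStatistics(
            mean_angle=stats1.mean_angle,
            mean_torque=stats1.mean_torque,
            var_angle=2 * stats1.var_angle,
            var_torque=2 * stats1.var_torque,
        )
        assert fit_metric(trace, stats2) == pytest.approx(fit_metric(trace, stats1) / 2)

    def test_short_simulation_rejected(self):
        trace = _flat_trace(n=50, duration=0.5)
        stats = BlockStatistics(
            mean_angle=np.zeros(256), mean_torque=np.zeros(256),
            var_angle=np.ones(256), var_torque=np.ones(256),
        )
        with pytest.raises(ShapeError, match="window"):
            fit_metric(trace, stats)

    def test_zero_variance_curve_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            floor_variances(np.zeros(256))

    def test_floor_applied_at_one_percent_of_mean(self):
        var = np.ones(100)
        var[0] = 0.0
        floored = floor_variances(var)
        assert floored[0] == pytest.approx(0.01 * var.mean())
        assert np.all(floored[1:] == 1.0)


class TestNeighborPermutations:
    def test_sixty_four_candidates_each_one_step_away(self):
        cfg = PlanSearchConfig()
        params = np.array([2.0, 0.1, 30.0, 2.0, 0.1, 30.0])
        cands = neighbor_permutations(params, cfg)
        assert cands.shape == (64, 6)
        assert len({tuple(c) for c in cands}) == 64
        np.testing.assert_allclose(
            np.abs(cands - params), np.tile(STEP, (64, 1))
        )

    def test_mirror_symmetry_before_clipping(self):
        cfg = PlanSearchConfig()
        params = np.array([5.0, 0.3, 30.0, 5.0, 0.3, 30.0])  # no clipping active
        cands = {tuple(c) for c in neighbor_permutations(params, cfg)}
        for c in list(cands):
            mirror = tuple(2 * params - np.array(c))
            assert mirror in cands

    def test_negative_weights_clipped_to_zero(self):
        cfg = PlanSearchConfig()
        params = np.array([0.5, 0.02, 30.0, 0.5, 0.02, 30.0])
        cands = neighbor_permutations(params, cfg)
        assert cands[:, [0, 1, 3, 4]].min() == 0.0


class TestTreeSearch:
    def test_recovers_known_lattice_plans(self):
        truth = np.array([2.0, 0.3, 28.0, 4.0, 0.2, 30.0])
        stats = noiseless_block_statistics(
            MotionPlan(truth[0], truth[1], theta_target=truth[2]),
            MotionPlan(truth[3], truth[4], theta_target=truth[5]),
        )
        result = tree_search_identify(stats)
        np.testing.assert_array_less(np.abs(result.params - truth), STEP + 1e-9)

    def test_symmetric_dyad_identified_symmetrically(self):
        plan = MotionPlan(3.0, 0.15, theta_target=31.0)
        stats = noiseless_block_statistics(plan, plan)
        result = tree_search_identify(stats)
        assert abs(result.plan1.q_pos - result.plan2.q_pos) <= 1.0 + 1e-9
        assert abs(result.plan1.q_vel - result.plan2.q_vel) <= 0.05 + 1e-9

    def test_best_not_worse_than_initialization(self):
        stats = noiseless_block_statistics(MotionPlan(4.0, 0.2), MotionPlan(1.0, 0.3))
        result = tree_search_identify(
            stats, PlanSearchConfig(n_iterations=30)
        )
        assert result.fit_metric <= result.search_path[0][1]

    def test_fit_metric_recomputable_from_returned_plans(self):
        stats = noiseless_block_statistics(MotionPlan(3.0, 0.1), MotionPlan(2.0, 0.2))
        result = tree_search_identify(stats, PlanSearchConfig(n_iterations=20))
        from dyadreach.identify import _evaluate_candidates

        M = _evaluate_candidates(
            result.params[None, :],
            stats,
            floor_variances(stats.var_angle),
            floor_variances(stats.var_torque),
            PlantParams(),
            SimSettings(),
        )[0]
        assert M == pytest.approx(result.fit_metric, rel=1e-12)

    def test_search_is_deterministic(self):
        stats = noiseless_block_statistics(MotionPlan(4.0, 0.2), MotionPlan(2.0, 0.1))
        cfg = PlanSearchConfig(n_iterations=15)
        r1 = tree_search_identify(stats, cfg)
        r2 = tree_search_identify(stats, cfg)
        assert len(r1.search_path) == len(r2.search_path)
        for (p1, m1), (p2, m2) in zip(r1.search_path, r2.search_path):
            np.testing.assert_array_equal(p1, p2)
            assert m1 == m2

    def test_weights_never_negative_along_path(self):
        stats = noiseless_block_statistics(MotionPlan(1.0, 0.05), MotionPlan(1.0, 0.05))
        result = tree_search_identify(stats, PlanSearchConfig(n_iterations=30))
        for params, _ in result.search_path:
            assert params[[0, 1, 3, 4]].min() >= 0.0

    def test_estimator_interface_exposes_fitted_plans(self):
        stats = noiseless_block_statistics(MotionPlan(3.0, 0.1), MotionPlan(2.0, 0.2))
        ident = MotionPlanIdentifier(n_iterations=10)
        assert ident.get_params()["n_iterations"] == 10
        ident.fit(stats)
        assert isinstance(ident.plan1_, MotionPlan)
        assert ident.fit_metric_ == ident.result_.fit_metric
        assert ident.score(stats) == -ident.fit_metric_


class TestSampleLatticePlans:
    def test_samples_lie_on_walkable_lattice(self, rng):
        cfg = PlanSearchConfig()
        for _ in range(20):
            truth = sample_lattice_plans(rng, cfg)
            disp = np.abs(truth - cfg.init_vector) / cfg.step_vector
            steps = np.round(disp).astype(int)
            np.testing.assert_allclose(disp, steps, atol=1e-9)
            assert len(set(steps % 2)) == 1  # uniform parity in every coordinate
            assert truth[[0, 3]].min() >= 1 and truth[[1, 4]].min() >= 0


class TestComparePlans:
    @staticmethod
    def _identified(qp1, qv1, qp2, qv2):
        return IdentifiedPlan(
            plan1=MotionPlan(qp1, qv1),
            plan2=MotionPlan(qp2, qv2),
            fit_metric=0.0,
        )

    def test_no_change_reports_zero_shift(self):
        a = self._identified(2, 0.1, 2, 0.1)
        shift = compare_plans(a, self._identified(2, 0.1, 2, 0.1), pusher=1)
        assert shift.shift == (0.0, 0.0)
        assert not shift.pusher_ratio_increased
        assert not shift.puller_ratio_decreased

    def test_expected_shift_pattern_detected(self):
        coupled = self._identified(2, 0.1, 2, 0.1)
        pushpull = self._identified(5, 0.1, 2, 0.4)  # pusher 1 up, puller 2 down
        shift = compare_plans(coupled, pushpull, pusher=1)
        assert shift.pusher_ratio_increased
        assert shift.puller_ratio_decreased

    def test_ratio_invariant_to_common_scaling(self):
        a = self._identified(2, 0.1, 4, 0.3)
        b = self._identified(20, 1.0, 40, 3.0)
        shift = compare_plans(a, b, pusher=1)
        assert shift.shift == (0.0, 0.0)

    def test_degenerate_plan_raises(self):
        good = self._identified(2, 0.1, 2, 0.1)
        bad = IdentifiedPlan(
            plan1=MotionPlan(0.0, 0.0), plan2=MotionPlan(2, 0.1), fit_metric=0.0
        )
        with pytest.raises(DegenerateDataError):
            compare_plans(good, bad, pusher=1)
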