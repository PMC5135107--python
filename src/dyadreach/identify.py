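"""Identification of both partners' motion plans from block-average data.

The six free parameters (q_pos, q_vel, theta_target for each partner)
are found by a greedy lattice search: from the current point, all 64
sign permutations of one step in every coordinate are simulated, the
candidate with the lowest normalised squared distance to the block-mean
angle and torque curves is adopted, and the process repeats for a fixed
number of iterations.  The reported answer is the best point visited
anywhere along the path, which guards against the corner-stepping
oscillation inherent to a move-every-coordinate scheme.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateDataError,
    ParameterError,
    SearchFailureError,
    ShapeError,
)
from .model import (
    MotionPlan,
    PlantParams,
    SimulationTrace,
    _check_duration,
    _simulate_dyad_batch,
    constrained_pushpull_state,
    gain_for,
)

__all__ = [
    "BlockStatistics",
    "PlanSearchConfig",
    "SimSettings",
    "IdentifiedPlan",
    "PlanShift",
    "floor_variances",
    "fit_metric",
    "neighbor_permutations",
    "tree_search_identify",
    "compare_plans",
    "noiseless_block_statistics",
    "sample_lattice_plans",
    "MotionPlanIdentifier",
]

#: Fraction of the block-wide mean variance used as the variance floor.
VARIANCE_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class BlockStatistics:
    """Per-sample mean and across-trial variance curves of one block.

    ``mean_angle`` is the average-cursor angle (deg) and ``mean_torque``
    the interaction torque (Nm, recording convention) averaged over all
    trials; the variance curves are the across-trial variances at each
    sample and weight the two terms of the fit metric.
    """

    mean_angle: np.ndarray
    mean_torque: np.ndarray
    var_angle: np.ndarray
    var_torque: np.ndarray
    n_trials: int = 30
    block_label: str = "coupled"

    def __post_init__(self) -> None:
        n = len(self.mean_angle)
        for name in ("mean_torque", "var_angle", "var_torque"):
            if len(getattr(self, name)) != n:
                raise ShapeError(
                    f"BlockStatistics.{name} has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if np.any(self.var_angle < 0) or np.any(self.var_torque < 0):
            raise ParameterError("variance curves must be nonnegative")

    def __len__(self) -> int:
        return len(self.mean_angle)


@dataclass(frozen=True)
class PlanSearchConfig:
    """Lattice steps, iteration budget and starting point of the search.

    ``restart_patience`` controls the deterministic intensification
    policy: after that many consecutive non-improving moves the walk
    returns to the incumbent best point (0 disables restarts).  With
    ``allow_revisit`` False the walk never re-expands a point it has
    already visited, which breaks the period-2 corner cycles the
    move-every-coordinate scheme is prone to.  Setting
    ``allow_revisit=True`` and ``restart_patience=0`` recovers the plain
    greedy walk.
    """

    step_qpos: float = 1.0
    step_qvel: float = 0.05
    step_theta: float = 1.0
    n_iterations: int = 200
    init_qpos: float = 2.0
    init_qvel: float = 0.1
    init_theta: float = 30.0
    allow_revisit: bool = False
    restart_patience: int = 10

    def __post_init__(self) -> None:
        for name in ("step_qpos", "step_qvel", "step_theta"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"PlanSearchConfig.{name} must be > 0")
        if self.n_iterations < 1:
            raise ParameterError("PlanSearchConfig.n_iterations must be >= 1")
        if self.restart_patience < 0:
            raise ParameterError("PlanSearchConfig.restart_patience must be >= 0")

    @property
    def step_vector(self) -> np.ndarray:
        return np.array(
            [self.step_qpos, self.step_qvel, self.step_theta] * 2, dtype=float
        )

    @property
    def init_vector(self) -> np.ndarray:
        return np.array(
            [self.init_qpos, self.init_qvel, self.init_theta] * 2, dtype=float
        )


@dataclass(frozen=True)
class SimSettings:
    """How candidate dyads are simulated during the search.

    ``block_type`` selects the initial condition: ``"coupled"`` starts
    both wrists at rest at ``theta_start``; ``"pushpull"`` starts from a
    pre-movement state holding opposing torques ``+-tau0`` (``tau0`` is
    partner 1's held torque, so its sign encodes who pushes).
    ``pushpull_start`` chooses between the state the controllers settle
    to under the pre-movement target (``"settled"``) and the exact
    equilibrium with the torque constraint enforced (``"constrained"``).
    The hold rule fires on ``task_target`` (the displayed target), not
    on the candidate plan targets.
    """

    block_type: str = "coupled"
    theta_start: float = -10.0
    tau0: float = 0.7
    r: float = 0.5
    task_target: float = 30.0
    duration: float = 1.2
    settle_time: float = 3.0
    hold_rule: bool = True
    pushpull_start: str = "settled"

    def __post_init__(self) -> None:
        if self.block_type not in ("coupled", "pushpull"):
            raise ParameterError(
                f"SimSettings.block_type must be 'coupled' or 'pushpull', "
                f"got {self.block_type!r}"
            )
        if self.pushpull_start not in ("settled", "constrained"):
            raise ParameterError(
                "SimSettings.pushpull_start must be 'settled' or 'constrained'"
            )


@dataclass(frozen=True)
class PlanShift:
    """Between-block change in each partner's position-priority ratio."""

    ratio_coupled: tuple[float, float]
    ratio_pushpull: tuple[float, float]
    shift: tuple[float, float]
    pusher: int
    pusher_ratio_increased: bool
    puller_ratio_decreased: bool


@dataclass
class IdentifiedPlan:
    """Result of one tree search: both plans, the metric, and the path."""

    plan1: MotionPlan
    plan2: MotionPlan
    fit_metric: float
    search_path: list[tuple[np.ndarray, float]] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [
                self.plan1.q_pos, self.plan1.q_vel, self.plan1.theta_target,
                self.plan2.q_pos, self.plan2.q_vel, self.plan2.theta_target,
            ]
        )


def floor_variances(var: np.ndarray, fraction: float = VARIANCE_FLOOR_FRACTION) -> np.ndarray:
    """Floor a variance curve at ``fraction`` of its block-wide mean.

    Prevents division blow-ups at samples where across-trial variance is
    near zero (e.g. before movement onset).  A curve whose mean is zero
    (all trials identical everywhere) cannot be floored meaningfully.
    """
    var = np.asarray(var, dtype=float)
    mean = var.mean()
    if not (mean > 0):
        raise DegenerateDataError(
            "variance curve is identically zero; the normalised metric is undefined"
        )
    return np.maximum(var, fraction * mean)


def _metric_curves(
    angle: np.ndarray,
    torque: np.ndarray,
    stats: BlockStatistics,
    var_angle: np.ndarray,
    var_torque: np.ndarray,
) -> np.ndarray:
    """Normalised squared distance for a batch of simulated curve pairs."""
    L = len(stats)
    da = angle - stats.mean_angle
    dq = torque - stats.mean_torque
    return (np.sum(da**2 / var_angle, axis=-1) + np.sum(dq**2 / var_torque, axis=-1)) / (
        2.0 * L
    )


def fit_metric(sim: SimulationTrace, stats: BlockStatistics, duration: float = 1.2) -> float:
    """Normalised squared distance between a simulation and block statistics.

    The simulated average-cursor angle and interaction torque (recording
    convention) are resampled onto the stats grid (``len(stats)`` samples
    over ``[0, duration]``) and compared against the block means, each
    squared residual weighted by the (floored) across-trial variance at
    that sample:

        M = (1 / 2L) * sum_i [ (mean_angle_i - angle_i)^2 / var_angle_i
                             + (mean_torque_i - torque_i)^2 / var_torque_i ]
    """
    L = len(stats)
    if sim.time[-1] + 1e-9 < duration:
        raise ShapeError(
            f"simulation spans {sim.time[-1]:.3f} s but the stats window is "
            f"{duration} s"
        )
    grid = np.linspace(0.0, duration, L)
    angle = np.interp(grid, sim.time, sim.average_angle)
    torque = np.interp(grid, sim.time, sim.data_torque)
    va = floor_variances(stats.var_angle)
    vt = floor_variances(stats.var_torque)
    return float(_metric_curves(angle, torque, stats, va, vt))


_SIGN_PATTERNS = np.array(list(itertools.product((-1.0, 1.0), repeat=6)))


def neighbor_permutations(params: np.ndarray, config: PlanSearchConfig) -> np.ndarray:
    """All 2^6 = 64 one-step sign permutations around the current point.

    Every coordinate moves by exactly +- its step; q_pos and q_vel are
    clipped at zero after stepping (the cost weights cannot be negative).
    """
    params = np.asarray(params, dtype=float)
    if params.shape != (6,):
        raise ShapeError(f"params must have shape (6,), got {params.shape}")
    cands = params + _SIGN_PATTERNS * config.step_vector
    cands[:, [0, 1, 3, 4]] = np.maximum(cands[:, [0, 1, 3, 4]], 0.0)
    return cands


def _resample_matrix_weights(n_source: int, dt: float, grid: np.ndarray):
    pos = grid / dt
    i0 = np.clip(np.floor(pos).astype(int), 0, n_source - 2)
    w = pos - i0
    return i0, w


def _candidate_curves(
    cands: np.ndarray,
    stats: BlockStatistics,
    plant: PlantParams,
    sim: SimSettings,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulated (angle, torque, diverged) for each candidate 6-vector,
    resampled onto the stats grid."""
    b = cands.shape[0]
    n_steps = _check_duration(sim.duration, plant.dt)
    L1 = np.empty((b, 4))
    L2 = np.empty((b, 4))
    with warnings.catch_warnings():
        # probing the q_pos = q_vel = 0 lattice corner is legitimate here
        warnings.simplefilter("ignore", UserWarning)
        for i, (qp1, qv1, _, qp2, qv2, _) in enumerate(cands):
            L1[i] = gain_for(MotionPlan(qp1, qv1, r=sim.r), plant)
            L2[i] = gain_for(MotionPlan(qp2, qv2, r=sim.r), plant)

    zeros = np.zeros(b)
    t1 = np.column_stack([cands[:, 2], zeros, zeros, zeros])
    t2 = np.column_stack([cands[:, 5], zeros, zeros, zeros])

    if sim.block_type == "coupled":
        x1 = np.tile([sim.theta_start, 0.0, 0.0, 0.0], (b, 1))
        x2 = x1.copy()
        diverged0 = np.zeros(b, dtype=bool)
    elif sim.pushpull_start == "constrained":
        s1, s2 = constrained_pushpull_state(plant, sim.theta_start, sim.tau0)
        x1 = np.tile(s1.to_array(), (b, 1))
        x2 = np.tile(s2.to_array(), (b, 1))
        diverged0 = np.zeros(b, dtype=bool)
    else:  # settle each candidate pair under the pre-movement targets
        n_settle = _check_duration(sim.settle_time, plant.dt)
        p1 = np.column_stack([np.full(b, sim.theta_start), zeros, np.full(b, sim.tau0), zeros])
        p2 = np.column_stack([np.full(b, sim.theta_start), zeros, np.full(b, -sim.tau0), zeros])
        x0 = np.tile([sim.theta_start, 0.0, 0.0, 0.0], (b, 1))
        X1, X2, _, _, _, diverged0 = _simulate_dyad_batch(
            plant, L1, L2, p1, p2, x0, x0.copy(), n_settle
        )
        x1, x2 = X1[:, -1], X2[:, -1]

    X1, X2, _, _, _, diverged = _simulate_dyad_batch(
        plant, L1, L2, t1, t2, x1, x2, n_steps,
        hold_rule=sim.hold_rule, hold_target=sim.task_target,
    )
    diverged |= diverged0

    grid = np.linspace(0.0, sim.duration, len(stats))
    i0, w = _resample_matrix_weights(n_steps + 1, plant.dt, grid)
    angle_src = 0.5 * (X1[:, :, 0] + X2[:, :, 0])
    torque_src = plant.stiffness * (X1[:, :, 0] - X2[:, :, 0]) + plant.damping * (
        X1[:, :, 1] - X2[:, :, 1]
    )
    angle = (1 - w) * angle_src[:, i0] + w * angle_src[:, i0 + 1]
    torque = (1 - w) * torque_src[:, i0] + w * torque_src[:, i0 + 1]
    return angle, torque, diverged


def _evaluate_candidates(
    cands: np.ndarray,
    stats: BlockStatistics,
    var_angle: np.ndarray,
    var_torque: np.ndarray,
    plant: PlantParams,
    sim: SimSettings,
) -> np.ndarray:
    """Metric for each candidate 6-vector; +inf where the simulation diverged."""
    angle, torque, diverged = _candidate_curves(cands, stats, plant, sim)
    with np.errstate(invalid="ignore", over="ignore"):
        M = _metric_curves(angle, torque, stats, var_angle, var_torque)
    M = np.where(diverged | ~np.isfinite(M), np.inf, M)
    return M


def tree_search_identify(
    stats: BlockStatistics,
    config: PlanSearchConfig | None = None,
    plant: PlantParams | None = None,
    sim_settings: SimSettings | None = None,
) -> IdentifiedPlan:
    """Greedy 64-permutation lattice search for both partners' plans.

    Starting from the configured initial point, each iteration simulates
    all 64 one-step sign permutations of the current 6-vector, adopts
    the best unvisited one (smallest normalised squared distance to the
    block statistics), and repeats; after ``restart_patience``
    consecutive non-improving moves the walk returns to the incumbent
    best point.  Candidates whose simulation diverges get an infinite
    metric; the returned estimate is the best point seen over the whole
    path (initial point included).  Deterministic given inputs.
    """
    config = config or PlanSearchConfig()
    plant = plant or PlantParams()
    sim = sim_settings or SimSettings()

    var_angle = floor_variances(stats.var_angle)
    var_torque = floor_variances(stats.var_torque)

    current = config.init_vector
    M0 = _evaluate_candidates(current[None, :], stats, var_angle, var_torque, plant, sim)[0]
    path: list[tuple[np.ndarray, float]] = [(current.copy(), float(M0))]
    best, best_M = current.copy(), float(M0)
    visited = {tuple(np.round(current, 6))}
    stale = 0

    for _ in range(config.n_iterations):
        cands = neighbor_permutations(current, config)
        M = _evaluate_candidates(cands, stats, var_angle, var_torque, plant, sim)
        if not np.isfinite(M).any():
            raise SearchFailureError("every candidate simulation diverged")
        order = np.argsort(M, kind="stable")  # stable: deterministic tie-break
        j = int(order[0])
        if not config.allow_revisit:
            j = next(
                (
                    int(o)
                    for o in order
                    if np.isfinite(M[o]) and tuple(np.round(cands[o], 6)) not in visited
                ),
                int(order[0]),
            )
        current = cands[j]
        visited.add(tuple(np.round(current, 6)))
        path.append((current.copy(), float(M[j])))
        if M[j] < best_M:
            best, best_M = current.copy(), float(M[j])
            stale = 0
        else:
            stale += 1
            if config.restart_patience and stale >= config.restart_patience:
                current = best.copy()
                stale = 0

    plan1 = MotionPlan(best[0], best[1], r=sim.r, theta_target=best[2],
                       theta_start=sim.theta_start)
    plan2 = MotionPlan(best[3], best[4], r=sim.r, theta_target=best[5],
                       theta_start=sim.theta_start)
    return IdentifiedPlan(plan1=plan1, plan2=plan2, fit_metric=best_M, search_path=path)


def compare_plans(
    coupled: IdentifiedPlan, pushpull: IdentifiedPlan, pusher: int
) -> PlanShift:
    """Between-block change in position priority, per partner.

    The position-priority ratio ``q_pos / (q_pos + q_vel)`` is invariant
    to common scaling of the weights, making it comparable across blocks.
    The expectation under the pushing/pulling manipulation is that the
    pusher's ratio rises relative to the coupled block and the puller's
    falls.
    """
    if pusher not in (1, 2):
        raise ParameterError("pusher must be 1 or 2")
    try:
        rc = (coupled.plan1.position_priority, coupled.plan2.position_priority)
        rp = (pushpull.plan1.position_priority, pushpull.plan2.position_priority)
    except ParameterError as exc:
        raise DegenerateDataError(f"degenerate plan: {exc}") from exc
    shift = (rp[0] - rc[0], rp[1] - rc[1])
    i_push, i_pull = pusher - 1, 2 - pusher
    return PlanShift(
        ratio_coupled=rc,
        ratio_pushpull=rp,
        shift=shift,
        pusher=pusher,
        pusher_ratio_increased=shift[i_push] > 0,
        puller_ratio_decreased=shift[i_pull] < 0,
    )


def noiseless_block_statistics(
    plan1: MotionPlan,
    plan2: MotionPlan,
    plant: PlantParams | None = None,
    sim_settings: SimSettings | None = None,
    var_angle: float = 1.0,
    var_torque: float = 0.01,
    n_samples: int = 256,
) -> BlockStatistics:
    """Block statistics of an idealised noise-free dyad with known plans.

    The mean curves are the deterministic coupled simulation of the two
    plans; because identical trials have zero across-trial variance (for
    which the normalised metric is undefined), the variance curves are
    constant weights reflecting the two channels' natural scales
    (default 1 deg^2 for angle, 0.01 Nm^2 for torque, i.e. 1 deg and
    0.1 Nm standard deviations).  Used by parameter-recovery studies.
    """
    plant = plant or PlantParams()
    sim = sim_settings or SimSettings()
    cand = np.array(
        [
            plan1.q_pos, plan1.q_vel, plan1.theta_target,
            plan2.q_pos, plan2.q_vel, plan2.theta_target,
        ]
    )
    # reuse the search's own forward model so stats and search agree exactly
    stats0 = BlockStatistics(
        mean_angle=np.zeros(n_samples),
        mean_torque=np.zeros(n_samples),
        var_angle=np.full(n_samples, var_angle),
        var_torque=np.full(n_samples, var_torque),
    )
    angle, torque, diverged = _candidate_curves(cand[None, :], stats0, plant, sim)
    if diverged[0]:
        raise SearchFailureError("reference dyad simulation diverged")
    return BlockStatistics(
        mean_angle=angle[0],
        mean_torque=torque[0],
        var_angle=np.full(n_samples, var_angle),
        var_torque=np.full(n_samples, var_torque),
        n_trials=1,
        block_label=sim.block_type,
    )


def sample_lattice_plans(
    rng: np.random.Generator,
    config: PlanSearchConfig | None = None,
    max_steps: int = 4,
) -> np.ndarray:
    """Draw a random ground-truth 6-vector on the search's walkable lattice.

    Because every iteration moves all six coordinates by one step, any
    point the search can visit has the same displacement parity (in
    steps, from the initial point) in every coordinate.  Ground truths
    are therefore drawn with a common random parity and per-coordinate
    step displacements up to ``max_steps``, rejecting draws with
    negative cost weights or non-positive position weights.
    """
    config = config or PlanSearchConfig()
    init, steps = config.init_vector, config.step_vector
    while True:
        parity = int(rng.integers(0, 2))
        mags = np.array(
            [rng.choice([1, 3] if parity else [0, 2, 4][: max_steps // 2 + 1])
             for _ in range(6)],
            dtype=float,
        )
        signs = rng.choice([-1.0, 1.0], size=6)
        truth = init + signs * mags * steps
        if truth[0] >= 1 and truth[3] >= 1 and truth[1] >= 0 and truth[4] >= 0:
            return truth


class MotionPlanIdentifier(BaseEstimator):
    """Estimator interface to the greedy lattice plan search.

    Parameters mirror :class:`PlanSearchConfig` and :class:`SimSettings`;
    ``fit`` takes a :class:`BlockStatistics` and exposes the identified
    plans as fitted attributes.

    Attributes
    ----------
    plan1_, plan2_ : MotionPlan
        Identified plan of each partner.
    fit_metric_ : float
        Normalised squared distance at the identified plans.
    search_path_ : list of (params, metric)
        The full greedy path, initial point first.
    """

    def __init__(
        self,
        step_qpos: float = 1.0,
        step_qvel: float = 0.05,
        step_theta: float = 1.0,
        n_iterations: int = 200,
        init_qpos: float = 2.0,
        init_qvel: float = 0.1,
        init_theta: float = 30.0,
        allow_revisit: bool = False,
        restart_patience: int = 10,
        block_type: str = "coupled",
        theta_start: float = -10.0,
        tau0: float = 0.7,
        r: float = 0.5,
        task_target: float = 30.0,
        duration: float = 1.2,
        settle_time: float = 3.0,
        hold_rule: bool = True,
        pushpull_start: str = "settled",
        plant: PlantParams | None = None,
    ):
        self.step_qpos = step_qpos
        self.step_qvel = step_qvel
        self.step_theta = step_theta
        self.n_iterations = n_iterations
        self.init_qpos = init_qpos
        self.init_qvel = init_qvel
        self.init_theta = init_theta
        self.allow_revisit = allow_revisit
        self.restart_patience = restart_patience
        self.block_type = block_type
        self.theta_start = theta_start
        self.tau0 = tau0
        self.r = r
        self.task_target = task_target
        self.duration = duration
        self.settle_time = settle_time
        self.hold_rule = hold_rule
        self.pushpull_start = pushpull_start
        self.plant = plant

    def _config(self) -> PlanSearchConfig:
        return PlanSearchConfig(
            step_qpos=self.step_qpos,
            step_qvel=self.step_qvel,
            step_theta=self.step_theta,
            n_iterations=self.n_iterations,
            init_qpos=self.init_qpos,
            init_qvel=self.init_qvel,
            init_theta=self.init_theta,
            allow_revisit=self.allow_revisit,
            restart_patience=self.restart_patience,
        )

    def _sim_settings(self) -> SimSettings:
        return SimSettings(
            block_type=self.block_type,
            theta_start=self.theta_start,
            tau0=self.tau0,
            r=self.r,
            task_target=self.task_target,
            duration=self.duration,
            settle_time=self.settle_time,
            hold_rule=self.hold_rule,
            pushpull_start=self.pushpull_start,
        )

    def fit(self, X: BlockStatistics, y=None) -> "MotionPlanIdentifier":
        """Run the search against one block's statistics."""
        result = tree_search_identify(
            X, self._config(), self.plant or PlantParams(), self._sim_settings()
        )
        self.result_ = result
        self.plan1_ = result.plan1
        self.plan2_ = result.plan2
        self.fit_metric_ = result.fit_metric
        self.search_path_ = result.search_path
        return self

    def score(self, X: BlockStatistics, y=None) -> float:
        """Negative fit metric (higher is better), for model selection APIs."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "result_")
        return -self.fit_metric_
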