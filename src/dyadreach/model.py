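"""Discrete-time model of one or two coupled wrist reaching controllers.

Each agent controls a one degree-of-freedom wrist whose state is the
4-vector ``x = [angle, angular velocity, torque, activation]`` (degrees,
deg/s, Nm, Nm).  The muscle is a second-order low-pass filter with time
constant ``tau_u`` acting on the motor command, and the controller is an
infinite-horizon discrete linear quadratic regulator (LQR) that penalises
squared position and velocity error against a target plus squared command.
Two agents may be rigidly coupled through a stiff virtual spring-damper;
each plans independently and feels the other only through the coupling
torque (co-activity: no joint plan).

Angles are kept in degrees throughout; the coupling stiffness is in
Nm/deg and the effective inertia is the matching numerical constant, so
the discrete dynamics are internally consistent without unit conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import (
    ConvergenceError,
    ParameterError,
    SettlingError,
    SimulationDivergenceError,
)

__all__ = [
    "WristState",
    "PlantParams",
    "MotionPlan",
    "SystemMatrices",
    "ControllerGain",
    "SimulationTrace",
    "build_system_matrices",
    "solve_lqr_gain",
    "gain_for",
    "simulate_solo",
    "simulate_dyad",
    "init_pushpull_state",
    "constrained_pushpull_state",
    "torsional_to_linear_stiffness",
]

#: Bound on |angle| beyond which a closed-loop run is declared divergent.
_DIVERGENCE_ANGLE = 1.0e6


@dataclass(frozen=True)
class WristState:
    """State of one wrist: ``[angle, angular_velocity, torque, activation]``.

    ``activation`` is the auxiliary first muscle-filter stage (units Nm);
    ``torque`` is the second stage, the torque actually applied to the
    wrist inertia.
    """

    angle: float
    angular_velocity: float
    torque: float
    activation: float

    def __post_init__(self) -> None:
        for name in ("angle", "angular_velocity", "torque", "activation"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"WristState.{name} must be finite")

    def to_array(self) -> np.ndarray:
        """Serialize to the fixed order (angle, velocity, torque, activation)."""
        return np.array(
            [self.angle, self.angular_velocity, self.torque, self.activation],
            dtype=float,
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "WristState":
        x = np.asarray(x, dtype=float)
        if x.shape != (4,):
            raise ParameterError(f"state vector must have shape (4,), got {x.shape}")
        return cls(*x.tolist())


@dataclass(frozen=True)
class PlantParams:
    """Physical constants of the wrist plant and the virtual coupling.

    Parameters
    ----------
    inertia : float
        Effective wrist inertia (numerically 0.1 in the deg-based unit
        system used throughout).
    dt : float
        Simulation time step in seconds (0.01 s, matching the 100 Hz
        recording rate).
    tau_u : float
        Muscle filter time constant in seconds (0.040 s); must exceed
        ``dt`` so the discrete filter pole ``1 - dt/tau_u`` stays in (0, 1).
    stiffness : float
        Coupling stiffness K in Nm/deg (0.4; the experimental value).
    damping : float
        Coupling damping D in Nm s/deg (0.05, modelling wrist damping).
    """

    inertia: float = 0.1
    dt: float = 0.01
    tau_u: float = 0.040
    stiffness: float = 0.4
    damping: float = 0.05

    def __post_init__(self) -> None:
        if not (self.inertia > 0):
            raise ParameterError("PlantParams.inertia must be > 0")
        if not (self.dt > 0):
            raise ParameterError("PlantParams.dt must be > 0")
        if not (self.tau_u > self.dt):
            raise ParameterError(
                "PlantParams.tau_u must exceed dt for a stable muscle filter"
            )
        if self.stiffness < 0:
            raise ParameterError("PlantParams.stiffness must be >= 0")
        if self.damping < 0:
            raise ParameterError("PlantParams.damping must be >= 0")

    def key(self) -> tuple:
        return (self.inertia, self.dt, self.tau_u, self.stiffness, self.damping)


@dataclass(frozen=True)
class MotionPlan:
    """One agent's motion plan: cost weights and reach target.

    The state cost matrix is ``Q = diag(q_pos, q_vel, 0, 0)`` (positive
    semi-definite by construction; torque and activation carry no cost)
    and the control cost is the positive scalar ``r``.  ``theta_target``
    is the reach target, ``theta_start`` the initial posture, and
    ``tau_pre`` an optional torque held against the partner before
    movement onset (0 when absent).
    """

    q_pos: float
    q_vel: float
    r: float = 0.5
    theta_target: float = 30.0
    theta_start: float = -10.0
    tau_pre: float = 0.0

    def __post_init__(self) -> None:
        if self.q_pos < 0:
            raise ParameterError("MotionPlan.q_pos must be >= 0")
        if self.q_vel < 0:
            raise ParameterError("MotionPlan.q_vel must be >= 0")
        if not (self.r > 0):
            raise ParameterError("MotionPlan.r must be > 0")

    @property
    def Q(self) -> np.ndarray:
        """Full 4x4 state-cost matrix diag(q_pos, q_vel, 0, 0)."""
        return np.diag([self.q_pos, self.q_vel, 0.0, 0.0])

    @property
    def position_priority(self) -> float:
        """Fraction of state cost on position, ``q_pos / (q_pos + q_vel)``."""
        s = self.q_pos + self.q_vel
        if s == 0:
            raise ParameterError("position_priority undefined for q_pos = q_vel = 0")
        return self.q_pos / s

    def reach_target_vector(self) -> np.ndarray:
        return np.array([self.theta_target, 0.0, 0.0, 0.0])

    def pre_movement_target_vector(self) -> np.ndarray:
        return np.array([self.theta_start, 0.0, self.tau_pre, 0.0])


@dataclass(frozen=True)
class SystemMatrices:
    """State transition A (4x4), input B (4x1) and coupling C (4x4)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray


@dataclass(frozen=True)
class ControllerGain:
    """Converged LQR solution: feedback gain L (1x4) and Riccati matrix S."""

    L: np.ndarray
    S: np.ndarray
    iterations_used: int
    residual: float


@dataclass
class SimulationTrace:
    """Time histories of a solo or dyadic closed-loop simulation.

    ``interaction_torque`` follows the partner-1 convention: the torque
    the coupling applies *to* partner 1,
    ``K (theta_2 - theta_1) + D (dtheta_2 - dtheta_1)``; partner 2 feels
    the exact negative.  ``data_torque`` flips the sign to the recording
    convention (positive = partner 1 pushing the shared cursor toward
    the target).
    """

    time: np.ndarray
    states: tuple[np.ndarray, ...]          # each (n_samples, 4)
    commands: tuple[np.ndarray, ...]        # each (n_samples - 1,)
    interaction_torque: np.ndarray          # (n_samples,), torque on partner 1
    plant: PlantParams
    hold_switch_index: int | None = None

    @property
    def n_partners(self) -> int:
        return len(self.states)

    def angle(self, partner: int = 0) -> np.ndarray:
        return self.states[partner][:, 0]

    @property
    def average_angle(self) -> np.ndarray:
        """Average-cursor angle (the quantity displayed and analysed)."""
        return np.mean([s[:, 0] for s in self.states], axis=0)

    @property
    def data_torque(self) -> np.ndarray:
        """Interaction torque in the recording sign convention."""
        return -self.interaction_torque


def torsional_to_linear_stiffness(torsional_stiffness: float, lever_arm: float) -> float:
    """Convert a torsional stiffness (Nm/rad) to the equivalent linear
    stiffness (N/m) felt at a lever arm (m) from the rotation centre.

    23 Nm/rad at a 0.1 m arm (wrist centre to mid-palm) gives 2300 N/m.
    """
    if lever_arm <= 0:
        raise ParameterError("lever_arm must be > 0")
    return torsional_stiffness / lever_arm**2


def build_system_matrices(plant: PlantParams, coupled: bool) -> SystemMatrices:
    """Construct the discrete A, B and coupling C matrices.

    ``A`` integrates angle and velocity, accelerates the wrist by
    ``torque / inertia`` and runs the two-stage muscle filter with the
    shared pole ``1 - dt/tau_u``; ``B`` feeds the motor command into the
    activation stage.  ``C`` injects the partner's relative angle and
    velocity into the acceleration row (spring-damper) and is zero when
    the partners are disconnected.
    """
    if not isinstance(plant, PlantParams):
        plant = PlantParams(*plant)  # permissive: accept a 5-tuple
    dt, I, tau = plant.dt, plant.inertia, plant.tau_u
    a = 1.0 - dt / tau
    A = np.array(
        [
            [1.0, dt, 0.0, 0.0],
            [0.0, 1.0, dt / I, 0.0],
            [0.0, 0.0, a, dt / tau],
            [0.0, 0.0, 0.0, a],
        ]
    )
    B = np.array([[0.0], [0.0], [0.0], [dt / tau]])
    C = np.zeros((4, 4))
    if coupled:
        C[1, 0] = plant.stiffness * dt / I
        C[1, 1] = plant.damping * dt / I
    return SystemMatrices(A=A, B=B, C=C)


def solve_lqr_gain(
    sys: SystemMatrices,
    plan: MotionPlan,
    tol: float = 1e-10,
    max_iter: int = 10**6,
) -> ControllerGain:
    """Solve the infinite-horizon discrete LQR by Riccati fixed-point iteration.

    Iterates ``S <- Q + A' [S - S B (R + B'SB)^-1 B'S] A`` from ``S = Q``,
    symmetrising each iterate, until the maximum absolute element change
    drops below ``tol``; the gain is ``L = (R + B'SB)^-1 B'S A``.  Each
    controller plans with the *uncoupled* A, B: the partner is not part
    of the plan, only of the world.

    Raises
    ------
    ConvergenceError
        If the element change is still above ``tol`` after ``max_iter``
        iterations (the residual is attached to the exception).
    """
    A, B = sys.A, sys.B
    Q = plan.Q
    R = plan.r
    if plan.q_pos == 0 and plan.q_vel == 0:
        warnings.warn(
            "q_pos = q_vel = 0: zero state cost yields the zero gain (no regulation)",
            stacklevel=2,
        )
        S = np.zeros((4, 4))
        return ControllerGain(L=np.zeros((1, 4)), S=S, iterations_used=0, residual=0.0)

    S = Q.astype(float).copy()
    residual = np.inf
    n = 0
    for n in range(1, max_iter + 1):
        SB = S @ B                                  # (4,1)
        gain_den = R + (B.T @ SB).item()            # scalar R + B'SB
        S_new = Q + A.T @ (S - (SB @ SB.T) / gain_den) @ A
        S_new = 0.5 * (S_new + S_new.T)
        residual = float(np.max(np.abs(S_new - S)))
        S = S_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"Riccati iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})",
            residual=residual,
        )
    assert float(np.max(np.abs(S - S.T))) < 1e-9
    L = (B.T @ S @ A) / (R + (B.T @ S @ B).item())
    return ControllerGain(L=L, S=S, iterations_used=n, residual=residual)


@lru_cache(maxsize=None)
def _cached_gain_vector(q_pos: float, q_vel: float, r: float, plant_key: tuple) -> tuple:
    plant = PlantParams(*plant_key)
    sys = build_system_matrices(plant, coupled=False)
    gain = solve_lqr_gain(sys, MotionPlan(q_pos=q_pos, q_vel=q_vel, r=r))
    return tuple(gain.L.ravel().tolist())


def gain_for(plan: MotionPlan, plant: PlantParams) -> np.ndarray:
    """Feedback gain L (shape (4,)) for a plan, memoised on (q_pos, q_vel, r, plant).

    The memoisation makes the 64-candidate tree search affordable: most
    candidates revisit previously solved (q_pos, q_vel) lattice points.
    """
    key = (round(plan.q_pos, 9), round(plan.q_vel, 9), round(plan.r, 9), plant.key())
    return np.array(_cached_gain_vector(*key))


# ---------------------------------------------------------------------------
# Simulation core
# ---------------------------------------------------------------------------

def _simulate_dyad_batch(
    plant: PlantParams,
    L1: np.ndarray,
    L2: np.ndarray,
    t1: np.ndarray,
    t2: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    n_steps: int,
    hold_rule: bool = False,
    hold_target: float | None = None,
    u_noise1: np.ndarray | None = None,
    u_noise2: np.ndarray | None = None,
):
    """Vectorised parallel simulation of a batch of coupled dyads.

    All per-partner arrays have leading batch dimension ``b``: gains and
    targets ``(b, 4)``, initial states ``(b, 4)``.  Optional motor-command
    noise arrays are ``(b, n_steps)``.  Returns state histories
    ``(b, n_steps + 1, 4)`` for both partners, command histories
    ``(b, n_steps)``, the hold-switch sample index per batch element
    (-1 where the rule never fired or is off) and a divergence mask.

    The hold rule: at the first sample where the average angle reaches
    ``hold_target``, each partner's target is replaced by its own current
    angle (zero velocity / torque / activation), freezing both agents at
    their respective postures and leaving any coupling torque sustained.
    """
    sys = build_system_matrices(plant, coupled=True)
    A_T = sys.A.T
    C_T = sys.C.T
    b_row = sys.B.ravel()

    b = x1.shape[0]
    t1 = np.array(t1, dtype=float, copy=True)
    t2 = np.array(t2, dtype=float, copy=True)
    x1 = np.array(x1, dtype=float, copy=True)
    x2 = np.array(x2, dtype=float, copy=True)
    X1 = np.empty((b, n_steps + 1, 4))
    X2 = np.empty((b, n_steps + 1, 4))
    U1 = np.empty((b, n_steps))
    U2 = np.empty((b, n_steps))
    X1[:, 0] = x1
    X2[:, 0] = x2
    hold_idx = np.full(b, -1, dtype=int)

    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            if hold_rule:
                avg = 0.5 * (x1[:, 0] + x2[:, 0])
                newly = (hold_idx < 0) & (avg >= hold_target)
                if np.any(newly):
                    hold_idx[newly] = k
                    t1[newly] = 0.0
                    t2[newly] = 0.0
                    t1[newly, 0] = x1[newly, 0]
                    t2[newly, 0] = x2[newly, 0]
            u1 = -np.einsum("bi,bi->b", L1, x1 - t1)
            u2 = -np.einsum("bi,bi->b", L2, x2 - t2)
            if u_noise1 is not None:
                u1 = u1 + u_noise1[:, k]
            if u_noise2 is not None:
                u2 = u2 + u_noise2[:, k]
            d = x2 - x1
            x1 = x1 @ A_T + b_row * u1[:, None] + d @ C_T
            x2 = x2 @ A_T + b_row * u2[:, None] - d @ C_T
            X1[:, k + 1] = x1
            X2[:, k + 1] = x2
            U1[:, k] = u1
            U2[:, k] = u2

    with np.errstate(invalid="ignore"):
        diverged = ~np.isfinite(x1).all(axis=1) | ~np.isfinite(x2).all(axis=1)
        diverged |= np.abs(X1[:, :, 0]).max(axis=1) > _DIVERGENCE_ANGLE
        diverged |= np.abs(X2[:, :, 0]).max(axis=1) > _DIVERGENCE_ANGLE
    return X1, X2, U1, U2, hold_idx, diverged


def _interaction_torque_on_1(plant: PlantParams, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    d = X2 - X1
    return plant.stiffness * d[..., 0] + plant.damping * d[..., 1]


def _check_duration(duration: float, dt: float) -> int:
    n = duration / dt
    if duration <= 0 or abs(n - round(n)) > 1e-9:
        raise ParameterError(
            f"duration ({duration} s) must be a positive multiple of dt ({dt} s)"
        )
    return int(round(n))


def simulate_solo(
    plan: MotionPlan,
    plant: PlantParams,
    x0: WristState,
    duration: float,
) -> SimulationTrace:
    """Simulate a single decoupled controller reaching for its target.

    Iterates ``x <- A x + B u`` with ``u = -L (x - t)``,
    ``t = [theta_target, 0, 0, 0]``.  The interaction-torque series of the
    returned trace is identically zero (no partner).
    """
    n_steps = _check_duration(duration, plant.dt)
    sys = build_system_matrices(plant, coupled=False)
    L = gain_for(plan, plant)
    t = plan.reach_target_vector()
    x = x0.to_array()
    X = np.empty((n_steps + 1, 4))
    U = np.empty(n_steps)
    X[0] = x
    A, b_row = sys.A, sys.B.ravel()
    for k in range(n_steps):
        u = -L @ (x - t)
        x = A @ x + b_row * u
        X[k + 1] = x
        U[k] = u
    if not np.isfinite(X).all() or np.abs(X[:, 0]).max() > _DIVERGENCE_ANGLE:
        raise SimulationDivergenceError("solo simulation diverged")
    time = np.arange(n_steps + 1) * plant.dt
    return SimulationTrace(
        time=time,
        states=(X,),
        commands=(U,),
        interaction_torque=np.zeros(n_steps + 1),
        plant=plant,
    )


def simulate_dyad(
    plan1: MotionPlan,
    plan2: MotionPlan,
    plant: PlantParams,
    x0_pair: tuple[WristState, WristState],
    duration: float,
    hold_rule: bool = False,
    hold_target: float | None = None,
) -> SimulationTrace:
    """Simulate two coupled controllers planning independently.

    Each partner runs its own LQR toward its own target while the
    spring-damper coupling exchanges equal and opposite torques.  With
    ``hold_rule`` enabled, both agents freeze at their current postures
    at the first sample where the average angle reaches ``hold_target``
    (defaults to the mean of the two plan targets); any coupling torque
    present at that moment is then sustained to the end of the run.
    """
    n_steps = _check_duration(duration, plant.dt)
    if hold_target is None:
        hold_target = 0.5 * (plan1.theta_target + plan2.theta_target)
    L1 = gain_for(plan1, plant)[None, :]
    L2 = gain_for(plan2, plant)[None, :]
    t1 = plan1.reach_target_vector()[None, :]
    t2 = plan2.reach_target_vector()[None, :]
    x1 = x0_pair[0].to_array()[None, :]
    x2 = x0_pair[1].to_array()[None, :]
    X1, X2, U1, U2, hold_idx, diverged = _simulate_dyad_batch(
        plant, L1, L2, t1, t2, x1, x2, n_steps,
        hold_rule=hold_rule, hold_target=hold_target,
    )
    if diverged[0]:
        raise SimulationDivergenceError("dyad simulation diverged")
    time = np.arange(n_steps + 1) * plant.dt
    return SimulationTrace(
        time=time,
        states=(X1[0], X2[0]),
        commands=(U1[0], U2[0]),
        interaction_torque=_interaction_torque_on_1(plant, X1[0], X2[0]),
        plant=plant,
        hold_switch_index=int(hold_idx[0]) if hold_idx[0] >= 0 else None,
    )


def init_pushpull_state(
    plan1: MotionPlan,
    plan2: MotionPlan,
    plant: PlantParams,
    theta0: float,
    tau0: float,
    settle_time: float = 3.0,
    velocity_tol: float = 0.1,
) -> tuple[WristState, WristState]:
    """Settle the coupled pair under pre-movement targets and return the state.

    Partner 1 tracks ``[theta0, 0, +tau0, 0]`` and partner 2 the opposite
    torque ``[theta0, 0, -tau0, 0]`` for ``settle_time`` seconds starting
    from rest at ``theta0``.  With zero torque weight in Q the controllers
    track the torque component of the target only weakly, so the settled
    torque can fall well short of ``tau0``; a warning (not an error) is
    issued when the settled average angle misses ``theta0`` by more than
    1 degree or the settled muscle torque misses ``+-tau0`` by more than
    0.05 Nm.  Use :func:`constrained_pushpull_state` for the equilibrium
    in which the torque constraint is exactly enforced.

    Raises
    ------
    SettlingError
        If either wrist still moves faster than ``velocity_tol`` deg/s at
        the end of the settle window.
    """
    n_steps = _check_duration(settle_time, plant.dt)
    L1 = gain_for(plan1, plant)[None, :]
    L2 = gain_for(plan2, plant)[None, :]
    t1 = np.array([[theta0, 0.0, tau0, 0.0]])
    t2 = np.array([[theta0, 0.0, -tau0, 0.0]])
    x0 = np.array([[theta0, 0.0, 0.0, 0.0]])
    X1, X2, _, _, _, diverged = _simulate_dyad_batch(
        plant, L1, L2, t1, t2, x0, x0.copy(), n_steps
    )
    if diverged[0]:
        raise SimulationDivergenceError("pre-movement settling diverged")
    x1, x2 = X1[0, -1], X2[0, -1]
    if abs(x1[1]) > velocity_tol or abs(x2[1]) > velocity_tol:
        raise SettlingError(
            f"wrists still moving after {settle_time} s settle "
            f"(|velocities| {abs(x1[1]):.3f}, {abs(x2[1]):.3f} deg/s)"
        )
    avg_angle = 0.5 * (x1[0] + x2[0])
    if abs(avg_angle - theta0) > 1.0:
        warnings.warn(
            f"settled average angle {avg_angle:.2f} deg is more than 1 deg from "
            f"theta0 = {theta0} deg",
            stacklevel=2,
        )
    if abs(x1[2] - tau0) > 0.05 or abs(x2[2] + tau0) > 0.05:
        warnings.warn(
            f"settled torques ({x1[2]:.3f}, {x2[2]:.3f}) Nm miss the held "
            f"+-{tau0} Nm by more than 0.05 Nm (zero torque weight in Q tracks "
            "the torque target only weakly)",
            stacklevel=2,
        )
    return WristState.from_array(x1), WristState.from_array(x2)


def constrained_pushpull_state(
    plant: PlantParams,
    theta0: float,
    tau0: float,
) -> tuple[WristState, WristState]:
    """Exact mechanical equilibrium with the pre-movement torque enforced.

    In the experiment the held opposing torque is enforced by visual
    feedback, not produced spontaneously by the reach controller.  The
    corresponding equilibrium has both wrists at rest, muscle torques at
    ``+-tau0``, and the angles split symmetrically about ``theta0`` by
    ``tau0 / stiffness`` so the coupling spring transmits exactly the
    held torque and every net wrist torque vanishes.
    """
    if tau0 != 0 and plant.stiffness == 0:
        raise ParameterError("cannot hold a nonzero torque with zero coupling stiffness")
    delta = 0.0 if tau0 == 0 else tau0 / (2.0 * plant.stiffness)
    x1 = WristState(theta0 + delta, 0.0, tau0, tau0)
    x2 = WristState(theta0 - delta, 0.0, -tau0, -tau0)
    return x1, x2
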