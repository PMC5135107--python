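"""Synthetic dyad recordings with the statistical structure the analysis needs.

The deterministic coupled-controller model produces identical trials;
real blocks do not.  The generator therefore adds three documented noise
sources — white motor-command noise, multiplicative trial-to-trial
jitter on the plan weights, and a random onset delay — plus smooth
(low-pass filtered) angle measurement noise, and emits raw 100 Hz
recordings shaped like the experiment's: a stationary pre-onset segment
(holding the constrained +-0.7 Nm torque in push-pull blocks), a reach
from -10 to +30 degrees under the hold rule, and at least 2 s of data.
Per-bin plan overrides can inject a mid-block change in motion plan for
power studies.  All randomness derives from (seed, trial_index), so
blocks are reproducible trial by trial.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal

from .errors import ParameterError, SimulationDivergenceError
from .model import (
    MotionPlan,
    PlantParams,
    _simulate_dyad_batch,
    constrained_pushpull_state,
    gain_for,
)
from .preprocess import TrialRecording

__all__ = ["NoiseSpec", "ScenarioSpec", "generate_trial", "generate_block"]

#: Corner frequency (Hz) of the smoothing filter applied to measurement noise.
#: Encoder + soft-tissue noise in wrist kinematics is smooth; white noise at
#: 100 Hz would alias into unphysical >5 deg/s velocity excursions.
_MEASUREMENT_NOISE_CUTOFF = 3.0


@dataclass(frozen=True)
class NoiseSpec:
    """Noise amplitudes and the master seed.

    ``motor_noise_sd`` (Nm) is added white to each motor command;
    ``plan_jitter_sd`` scales the per-trial multiplicative jitter on
    q_pos and q_vel; ``onset_jitter_sd`` (s) delays movement start;
    ``measurement_noise_sd`` (deg) scales smooth additive angle noise.
    """

    motor_noise_sd: float = 0.02
    plan_jitter_sd: float = 0.05
    onset_jitter_sd: float = 0.05
    measurement_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "motor_noise_sd",
            "plan_jitter_sd",
            "onset_jitter_sd",
            "measurement_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"NoiseSpec.{name} must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """One block's ground truth: plans, block type and timing.

    ``bin_overrides`` maps bin numbers (1-6) to replacement
    ``(plan1, plan2)`` pairs, letting a scenario change the motion plan
    partway through the block.  ``tau0`` is the held pre-movement torque
    magnitude; ``pusher`` says which partner pushes toward the target in
    a push-pull block.
    """

    plan1: MotionPlan
    plan2: MotionPlan
    block_type: str = "coupled"
    block_label: str = ""
    pusher: int = 1
    tau0: float = 0.7
    n_trials: int = 30
    pre_movement_duration: float = 0.6
    total_duration: float = 2.2
    task_target: float = 30.0
    theta_start: float = -10.0
    dyad_id: str = "sim"
    plant: PlantParams = field(default_factory=PlantParams)
    bin_overrides: dict[int, tuple[MotionPlan, MotionPlan]] | None = None

    def __post_init__(self) -> None:
        if self.block_type not in ("coupled", "pushpull"):
            raise ParameterError("ScenarioSpec.block_type must be 'coupled' or 'pushpull'")
        if self.pusher not in (1, 2):
            raise ParameterError("ScenarioSpec.pusher must be 1 or 2")
        if self.bin_overrides:
            bad = [b for b in self.bin_overrides if not 1 <= b <= 6]
            if bad:
                raise ParameterError(f"bin_overrides reference invalid bins {bad}")
        if self.total_duration < self.pre_movement_duration + 1.3:
            raise ParameterError(
                "total_duration must leave at least 1.3 s after the pre-movement segment"
            )

    @property
    def label(self) -> str:
        return self.block_label or self.block_type

    def plans_for_trial(self, trial_index: int) -> tuple[MotionPlan, MotionPlan]:
        bin_number = (trial_index - 1) // 5 + 1
        if self.bin_overrides and bin_number in self.bin_overrides:
            return self.bin_overrides[bin_number]
        return self.plan1, self.plan2


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, fs: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    pad = 100  # generate extra samples and keep the centre: avoids filter edge transients
    white = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(2, _MEASUREMENT_NOISE_CUTOFF, btype="low", fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos, white)[pad : pad + n]
    scale = smooth.std()
    return smooth * (sd / scale) if scale > 0 else np.zeros(n)


def generate_trial(
    scn: ScenarioSpec, noise: NoiseSpec, trial_index: int
) -> TrialRecording:
    """Simulate one raw trial of the scenario at 100 Hz.

    The pre-onset segment holds the appropriate equilibrium (rest for
    coupled blocks; the constrained opposing-torque equilibrium for
    push-pull blocks) for the pre-movement duration plus onset jitter;
    the reach then runs the coupled controllers with the hold rule and
    per-step motor noise.  With all noise amplitudes zero the trial is
    fully deterministic and identical across trial indices.
    """
    if not 1 <= trial_index <= scn.n_trials:
        raise ParameterError(
            f"trial_index {trial_index} outside 1..{scn.n_trials}"
        )
    plant = scn.plant
    dt = plant.dt
    fs = 1.0 / dt
    rng = np.random.default_rng([noise.seed, trial_index])

    base1, base2 = scn.plans_for_trial(trial_index)
    jitter = rng.normal(0.0, noise.plan_jitter_sd, size=4) if noise.plan_jitter_sd else np.zeros(4)
    plan1 = MotionPlan(
        q_pos=max(base1.q_pos * (1 + jitter[0]), 0.0),
        q_vel=max(base1.q_vel * (1 + jitter[1]), 0.0),
        r=base1.r, theta_target=base1.theta_target, theta_start=scn.theta_start,
    )
    plan2 = MotionPlan(
        q_pos=max(base2.q_pos * (1 + jitter[2]), 0.0),
        q_vel=max(base2.q_vel * (1 + jitter[3]), 0.0),
        r=base2.r, theta_target=base2.theta_target, theta_start=scn.theta_start,
    )

    onset_delay = rng.normal(0.0, noise.onset_jitter_sd) if noise.onset_jitter_sd else 0.0
    pre_time = max(scn.pre_movement_duration + onset_delay, 2 * dt)
    n_pre = int(round(pre_time / dt))
    n_total = int(round(scn.total_duration / dt))
    n_reach = n_total - n_pre

    if scn.block_type == "pushpull":
        tau0_signed = scn.tau0 if scn.pusher == 1 else -scn.tau0
        s1, s2 = constrained_pushpull_state(plant, scn.theta_start, tau0_signed)
        x1_0, x2_0 = s1.to_array(), s2.to_array()
    else:
        x1_0 = np.array([scn.theta_start, 0.0, 0.0, 0.0])
        x2_0 = x1_0.copy()

    L1 = gain_for(plan1, plant)[None, :]
    L2 = gain_for(plan2, plant)[None, :]
    t1 = plan1.reach_target_vector()[None, :]
    t2 = plan2.reach_target_vector()[None, :]
    u_noise1 = u_noise2 = None
    if noise.motor_noise_sd:
        u_noise1 = rng.normal(0.0, noise.motor_noise_sd, size=(1, n_reach))
        u_noise2 = rng.normal(0.0, noise.motor_noise_sd, size=(1, n_reach))
    X1, X2, _, _, _, diverged = _simulate_dyad_batch(
        plant, L1, L2, t1, t2, x1_0[None, :], x2_0[None, :], n_reach,
        hold_rule=True, hold_target=scn.task_target,
        u_noise1=u_noise1, u_noise2=u_noise2,
    )
    if diverged[0]:
        raise SimulationDivergenceError(
            f"trial {trial_index} of scenario {scn.label!r} diverged"
        )

    angle1 = np.concatenate([np.full(n_pre, x1_0[0]), X1[0, 1:, 0]])
    angle2 = np.concatenate([np.full(n_pre, x2_0[0]), X2[0, 1:, 0]])
    vel1 = np.concatenate([np.zeros(n_pre), X1[0, 1:, 1]])
    vel2 = np.concatenate([np.zeros(n_pre), X2[0, 1:, 1]])
    # recording convention: positive = partner 1 pushing the cursor to the target
    torque = plant.stiffness * (angle1 - angle2) + plant.damping * (vel1 - vel2)

    angle1 = angle1 + _smooth_noise(rng, n_total, noise.measurement_noise_sd, fs)
    angle2 = angle2 + _smooth_noise(rng, n_total, noise.measurement_noise_sd, fs)

    return TrialRecording(
        angle1=angle1,
        angle2=angle2,
        interaction_torque=torque,
        sample_rate=fs,
        dyad_id=scn.dyad_id,
        block_label=scn.label,
        trial_index=trial_index,
    )


def generate_block(
    scn: ScenarioSpec, noise: NoiseSpec
) -> tuple[list[TrialRecording], dict]:
    """Generate all trials of a block plus a ground-truth manifest.

    The manifest records the seed, the scenario's nominal plans and each
    trial's effective (bin-resolved) base plans, supporting round-trip
    recovery tests downstream.
    """
    trials = [generate_trial(scn, noise, i) for i in range(1, scn.n_trials + 1)]
    manifest = {
        "seed": noise.seed,
        "dyad_id": scn.dyad_id,
        "block_label": scn.label,
        "block_type": scn.block_type,
        "pusher": scn.pusher,
        "tau0": scn.tau0,
        "noise": asdict(noise),
        "trials": [
            {
                "trial_index": i,
                "plan1": asdict(scn.plans_for_trial(i)[0]),
                "plan2": asdict(scn.plans_for_trial(i)[1]),
            }
            for i in range(1, scn.n_trials + 1)
        ],
    }
    return trials, manifest
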