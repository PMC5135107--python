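"""Raw recordings to analysis-ready curves.

A raw 100 Hz trial (both wrist angles + interaction torque) is turned
into the fixed analysis representation in a fixed order: movement onset
is detected from a velocity threshold on the raw average-cursor angle,
the series are truncated to the 1.2 s window after onset, linearly
resampled to 256 samples, and zero-phase low-pass filtered.  A 30-trial
block is then grouped into 6 chronological bins of 5 trials and reduced
to per-sample mean/variance curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    CountError,
    NoMovementError,
    ParameterError,
    ShapeError,
    TruncationError,
)
from .identify import BlockStatistics

__all__ = [
    "TrialRecording",
    "ProcessedTrial",
    "BinnedBlock",
    "detect_movement_onset",
    "align_truncate_resample",
    "lowpass_zero_phase",
    "process_trial",
    "bin_block",
    "block_statistics",
    "TrialPreprocessor",
    "ANALYSIS_WINDOW",
    "N_ANALYSIS_SAMPLES",
]

ANALYSIS_WINDOW = 1.2      # s kept after movement onset
N_ANALYSIS_SAMPLES = 256   # samples of the analysis grid
N_BINS = 6
TRIALS_PER_BIN = 5


@dataclass(frozen=True)
class TrialRecording:
    """One raw trial: both wrist angles and the coupling torque at 100 Hz."""

    angle1: np.ndarray
    angle2: np.ndarray
    interaction_torque: np.ndarray
    sample_rate: float = 100.0
    dyad_id: str = "sim"
    block_label: str = "coupled"
    trial_index: int = 1

    def __post_init__(self) -> None:
        n = len(self.angle1)
        if len(self.angle2) != n or len(self.interaction_torque) != n:
            raise ShapeError("angle1, angle2 and interaction_torque must share a length")
        if not (self.sample_rate > 0):
            raise ParameterError("TrialRecording.sample_rate must be > 0")
        if self.trial_index < 1:
            raise ParameterError("TrialRecording.trial_index must be >= 1")

    def __len__(self) -> int:
        return len(self.angle1)

    @property
    def average_angle(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.angle1) + np.asarray(self.angle2))

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate


@dataclass(frozen=True)
class ProcessedTrial:
    """Analysis curves of one trial: 256 samples spanning [0, 1.2] s."""

    angle: np.ndarray
    torque: np.ndarray
    onset_index: int

    def __post_init__(self) -> None:
        if len(self.angle) != N_ANALYSIS_SAMPLES or len(self.torque) != N_ANALYSIS_SAMPLES:
            raise ShapeError(
                f"processed curves must have {N_ANALYSIS_SAMPLES} samples"
            )


@dataclass(frozen=True)
class BinnedBlock:
    """Six chronological bins of five processed trials each."""

    bins: tuple[tuple[ProcessedTrial, ...], ...]

    def __post_init__(self) -> None:
        if len(self.bins) != N_BINS or any(len(b) != TRIALS_PER_BIN for b in self.bins):
            raise CountError(f"need {N_BINS} bins of {TRIALS_PER_BIN} trials")

    @property
    def trials(self) -> tuple[ProcessedTrial, ...]:
        return tuple(t for b in self.bins for t in b)

    def angle_array(self) -> np.ndarray:
        """(6, 5, 256) array of average-cursor angle curves."""
        return np.array([[t.angle for t in b] for b in self.bins])

    def torque_array(self) -> np.ndarray:
        """(6, 5, 256) array of interaction-torque curves."""
        return np.array([[t.torque for t in b] for b in self.bins])


def detect_movement_onset(rec: TrialRecording, threshold: float = 5.0) -> int:
    """First raw sample whose average-cursor speed exceeds ``threshold`` deg/s.

    Velocity is a central finite difference of the raw (unfiltered)
    average of the two wrist angles; edges use one-sided differences.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    velocity = np.gradient(rec.average_angle, 1.0 / rec.sample_rate)
    above = np.flatnonzero(np.abs(velocity) > threshold)
    if above.size == 0:
        raise NoMovementError(
            f"average-cursor speed never exceeded {threshold} deg/s"
        )
    return int(above[0])


def align_truncate_resample(
    rec: TrialRecording,
    onset: int,
    duration: float = ANALYSIS_WINDOW,
    n_samples: int = N_ANALYSIS_SAMPLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Slice ``[onset, onset + duration]`` and resample to a uniform grid.

    Linear interpolation onto ``n_samples`` points covering ``[0,
    duration]`` inclusive of both ends; exact for affine segments of the
    input, and endpoint-preserving when the window boundary falls on a
    raw sample.  Returns the (average-cursor angle, torque) pair.
    """
    fs = rec.sample_rate
    available = (len(rec) - 1 - onset) / fs
    if available + 1e-12 < duration:
        raise TruncationError(
            f"recording extends only {available:.3f} s past onset; "
            f"{duration} s required"
        )
    t_rel = np.arange(len(rec)) / fs - onset / fs
    grid = np.linspace(0.0, duration, n_samples)
    angle = np.interp(grid, t_rel, rec.average_angle)
    torque = np.interp(grid, t_rel, np.asarray(rec.interaction_torque, dtype=float))
    return angle, torque


def lowpass_zero_phase(
    curve: np.ndarray,
    cutoff: float = 6.0,
    order: int = 6,
    sample_rate: float = (N_ANALYSIS_SAMPLES - 1) / ANALYSIS_WINDOW,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass on an analysis-grid curve.

    A filter of the given design order is applied forward and backward
    (squared magnitude response, zero net phase).  ``sample_rate``
    defaults to the analysis grid rate, 255/1.2 = 212.5 Hz.  Edges are
    handled by reflective padding of length 3x the filter order.
    """
    curve = np.asarray(curve, dtype=float)
    nyquist = 0.5 * sample_rate
    if cutoff >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below the grid Nyquist {nyquist:.1f} Hz"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, curve, padtype="even", padlen=3 * order)


def process_trial(
    rec: TrialRecording,
    onset_threshold: float = 5.0,
    cutoff: float = 6.0,
    filter_order: int = 6,
) -> ProcessedTrial:
    """Full per-trial pipeline in the fixed order align-truncate-resample-filter."""
    onset = detect_movement_onset(rec, threshold=onset_threshold)
    angle, torque = align_truncate_resample(rec, onset)
    return ProcessedTrial(
        angle=lowpass_zero_phase(angle, cutoff=cutoff, order=filter_order),
        torque=lowpass_zero_phase(torque, cutoff=cutoff, order=filter_order),
        onset_index=onset,
    )


def bin_block(trials: list[ProcessedTrial]) -> BinnedBlock:
    """Group exactly 30 chronologically ordered trials into 6 bins of 5."""
    n = N_BINS * TRIALS_PER_BIN
    if len(trials) != n:
        raise CountError(f"need exactly {n} trials, got {len(trials)}")
    bins = tuple(
        tuple(trials[b * TRIALS_PER_BIN : (b + 1) * TRIALS_PER_BIN])
        for b in range(N_BINS)
    )
    return BinnedBlock(bins=bins)


def block_statistics(
    trials: list[ProcessedTrial],
    n_trials: int | None = None,
    block_label: str = "coupled",
) -> BlockStatistics:
    """Per-sample mean and unbiased (n-1) variance across a block's trials."""
    if len(trials) < 2:
        raise CountError("variance needs at least 2 trials")
    angles = np.array([t.angle for t in trials])
    torques = np.array([t.torque for t in trials])
    return BlockStatistics(
        mean_angle=angles.mean(axis=0),
        mean_torque=torques.mean(axis=0),
        var_angle=angles.var(axis=0, ddof=1),
        var_torque=torques.var(axis=0, ddof=1),
        n_trials=len(trials),
        block_label=block_label,
    )


class TrialPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping the per-trial pipeline.

    ``transform`` maps a list of :class:`TrialRecording` to a list of
    :class:`ProcessedTrial`; ``fit`` is a no-op kept for pipeline
    compatibility.
    """

    def __init__(
        self,
        onset_threshold: float = 5.0,
        cutoff: float = 6.0,
        filter_order: int = 6,
    ):
        self.onset_threshold = onset_threshold
        self.cutoff = cutoff
        self.filter_order = filter_order

    def fit(self, X=None, y=None) -> "TrialPreprocessor":
        return self

    def transform(self, X: list[TrialRecording]) -> list[ProcessedTrial]:
        return [
            process_trial(
                rec,
                onset_threshold=self.onset_threshold,
                cutoff=self.cutoff,
                filter_order=self.filter_order,
            )
            for rec in X
        ]
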