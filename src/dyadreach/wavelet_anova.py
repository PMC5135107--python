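"""Wavelet-domain functional ANOVA for trial-by-trial curve comparison.

Each 256-sample curve is expanded on an orthogonal coiflet-3 basis
(4 decomposition levels, periodized boundaries) giving exactly 256
coefficients.  A one-way fixed-effects ANOVA with bin (6 chronological
groups of 5 trials) as the factor is run per coefficient; coefficients
with a significant omnibus F test enter Scheffe pairwise contrasts
between all 15 bin pairs at a Bonferroni-adjusted level.  Masked
coefficient differences are transformed back to the time domain, giving
curves that are exactly zero wherever no significant difference exists.
A per-sample time-domain ANOVA corroborates the wavelet findings.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats as sstats
from sklearn.base import BaseEstimator

from .errors import ShapeError

__all__ = [
    "WaveletSpectrum",
    "CoefficientAnovaResult",
    "PosthocResult",
    "DifferenceCurveSet",
    "wavelet_transform",
    "inverse_wavelet",
    "wavelet_transform_batch",
    "inverse_wavelet_batch",
    "per_coefficient_anova",
    "scheffe_posthoc",
    "build_difference_curves",
    "pointwise_time_anova",
    "WaveletBinAnova",
    "BIN_PAIRS",
]

WAVELET = "coif3"
LEVEL = 4
MODE = "periodization"
N_SAMPLES = 256
N_BINS = 6
TRIALS_PER_BIN = 5
#: All 15 unordered bin pairs, 1-based, lexicographic.
BIN_PAIRS: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(1, N_BINS + 1), 2)
)
#: Reconstructed values with magnitude below this are numerical zero.
ZERO_TOL = 1e-9

# Coefficient layout for a 256-sample periodized level-4 decomposition:
# approximation level 4 first, then details level 4 down to level 1.
_COEFF_LENGTHS = (16, 16, 32, 64, 128)
_COEFF_SLICES = tuple(
    slice(a, a + n)
    for a, n in zip(np.concatenate([[0], np.cumsum(_COEFF_LENGTHS)[:-1]]), _COEFF_LENGTHS)
)


@dataclass(frozen=True)
class WaveletSpectrum:
    """256 wavelet coefficients in the fixed order [cA4, cD4, cD3, cD2, cD1]."""

    coefficients: np.ndarray
    family: str = WAVELET
    level: int = LEVEL
    boundary_mode: str = MODE

    def __post_init__(self) -> None:
        if len(self.coefficients) != N_SAMPLES:
            raise ShapeError(
                f"spectrum must hold {N_SAMPLES} coefficients, got "
                f"{len(self.coefficients)}"
            )


@dataclass(frozen=True)
class CoefficientAnovaResult:
    """Per-position one-way ANOVA across bins (256 F tests)."""

    F: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    df: tuple[int, int] = (N_BINS - 1, N_BINS * (TRIALS_PER_BIN - 1))

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


@dataclass(frozen=True)
class PosthocResult:
    """Scheffe pairwise significance: one row per bin pair, one column per position."""

    mask: np.ndarray                       # (15, n_positions) bool
    pairs: tuple[tuple[int, int], ...] = BIN_PAIRS
    n_omnibus_significant: int = 0
    adjusted_alpha: float | None = None


@dataclass
class DifferenceCurveSet:
    """Time-domain difference curves between every bin pair.

    ``wavelet_significant`` is the inverse transform of the bin-mean
    coefficient differences masked to post-hoc-significant positions; it
    is identically zero for a pair with no significant coefficient.
    ``pointwise_significant`` (present when time-domain curves were
    supplied) masks the raw mean difference to samples flagged by the
    time-domain corroboration analysis.
    """

    pairs: tuple[tuple[int, int], ...]
    time: np.ndarray
    mean_difference: np.ndarray            # (15, 256)
    wavelet_significant: np.ndarray        # (15, 256)
    windows: list[list[tuple[float, float]]]
    pointwise_significant: np.ndarray | None = None


def _split(coeffs: np.ndarray) -> list[np.ndarray]:
    return [coeffs[..., s] for s in _COEFF_SLICES]


def wavelet_transform_batch(curves: np.ndarray) -> np.ndarray:
    """Forward transform along the last axis of an array of 256-sample curves."""
    curves = np.asarray(curves, dtype=float)
    if curves.shape[-1] != N_SAMPLES:
        raise ShapeError(f"curves must have {N_SAMPLES} samples, got {curves.shape[-1]}")
    with warnings.catch_warnings():
        # 4 levels exceed pywt's conservative depth heuristic for a
        # length-18 filter on 256 samples; periodization still gives an
        # exactly invertible 256-coefficient transform.
        warnings.simplefilter("ignore", UserWarning)
        parts = pywt.wavedec(curves, WAVELET, mode=MODE, level=LEVEL, axis=-1)
    return np.concatenate(parts, axis=-1)


def inverse_wavelet_batch(coeffs: np.ndarray) -> np.ndarray:
    """Inverse transform along the last axis; exact inverse of the forward."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != N_SAMPLES:
        raise ShapeError(
            f"need {N_SAMPLES} coefficients, got {coeffs.shape[-1]}"
        )
    return pywt.waverec(_split(coeffs), WAVELET, mode=MODE, axis=-1)


def wavelet_transform(curve: np.ndarray) -> WaveletSpectrum:
    """Periodized coiflet-3 level-4 transform of one 256-sample curve."""
    return WaveletSpectrum(coefficients=wavelet_transform_batch(np.asarray(curve)))


def inverse_wavelet(spec: WaveletSpectrum | np.ndarray) -> np.ndarray:
    """Reconstruct the 256-sample curve from a spectrum."""
    coeffs = spec.coefficients if isinstance(spec, WaveletSpectrum) else np.asarray(spec)
    return inverse_wavelet_batch(coeffs)


def _as_binned_array(binned) -> np.ndarray:
    """Coerce input to a (6, 5, n_positions) float array."""
    arr = np.asarray(binned, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == N_BINS * TRIALS_PER_BIN:
        arr = arr.reshape(N_BINS, TRIALS_PER_BIN, -1)
    if arr.ndim != 3 or arr.shape[:2] != (N_BINS, TRIALS_PER_BIN):
        raise ShapeError(
            f"expected ({N_BINS}, {TRIALS_PER_BIN}, n) or "
            f"({N_BINS * TRIALS_PER_BIN}, n) data, got {arr.shape}"
        )
    return arr


def _oneway_f(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised balanced one-way ANOVA over axis (bins, trials, positions).

    Returns (F, p, MSE).  Positions where both the between- and
    within-group sums of squares vanish (constant data) get F = 0,
    p = 1: degenerate data carries no evidence of change.
    """
    k, n, _ = arr.shape
    dfb, dfw = k - 1, k * (n - 1)
    group_mean = arr.mean(axis=1)                      # (k, P)
    grand = group_mean.mean(axis=0)                    # (P,)
    ssb = n * ((group_mean - grand) ** 2).sum(axis=0)
    ssw = ((arr - group_mean[:, None, :]) ** 2).sum(axis=(0, 1))
    # constant data leaves rounding crumbs of order eps^2 * scale in the
    # sums of squares; treat those as exact zeros
    scale = (arr**2).sum(axis=(0, 1))
    tiny = 1e-24 * np.maximum(scale, 1e-300)
    ssb = np.where(ssb <= tiny, 0.0, ssb)
    ssw = np.where(ssw <= tiny, 0.0, ssw)
    msb = ssb / dfb
    mse = ssw / dfw
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / mse
    F = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), F)
    p = sstats.f.sf(F, dfb, dfw)
    p = np.where(np.isinf(F), 0.0, np.where((ssw == 0) & (ssb == 0), 1.0, p))
    return F, p, mse


def per_coefficient_anova(binned, alpha: float = 0.05) -> CoefficientAnovaResult:
    """One-way fixed-effects ANOVA across bins at every coefficient position.

    ``binned`` is a (6, 5, 256) array of spectra (or (30, 256) in
    chronological order).  With 6 bins of 5 trials the F statistics have
    (5, 24) degrees of freedom; positions with p < alpha are flagged.
    """
    arr = _as_binned_array(binned)
    F, p, _ = _oneway_f(arr)
    return CoefficientAnovaResult(F=F, p=p, significant=p < alpha, alpha=alpha)


def scheffe_posthoc(
    binned,
    anova: CoefficientAnovaResult,
    alpha: float = 0.05,
) -> PosthocResult:
    """Scheffe pairwise bin contrasts at the Bonferroni-adjusted level.

    Only positions with a significant omnibus F are tested.  For bins
    ``i, j`` the contrast statistic ``(mean_i - mean_j)^2 / (MSE (1/n +
    1/n))`` is compared with ``(k - 1) F_crit(alpha / m; k - 1, N - k)``
    where ``m`` is the number of significant omnibus tests.  With m = 0
    the mask is empty (nothing to test, not an error).
    """
    arr = _as_binned_array(binned)
    m = anova.n_significant
    mask = np.zeros((len(BIN_PAIRS), arr.shape[-1]), dtype=bool)
    if m == 0:
        return PosthocResult(mask=mask, n_omnibus_significant=0, adjusted_alpha=None)
    k, n, _ = arr.shape
    dfb, dfw = k - 1, k * (n - 1)
    adj_alpha = alpha / m
    crit = dfb * sstats.f.isf(adj_alpha, dfb, dfw)
    _, _, mse = _oneway_f(arr)
    group_mean = arr.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        for row, (b1, b2) in enumerate(BIN_PAIRS):
            diff2 = (group_mean[b1 - 1] - group_mean[b2 - 1]) ** 2
            stat = diff2 / (mse * (2.0 / n))
            stat = np.where(mse == 0, np.where(diff2 == 0, 0.0, np.inf), stat)
            mask[row] = anova.significant & (stat > crit)
    return PosthocResult(mask=mask, n_omnibus_significant=m, adjusted_alpha=adj_alpha)


def _runs_above(values: np.ndarray, time: np.ndarray, tol: float) -> list[tuple[float, float]]:
    above = np.abs(values) > tol
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(values) - 1)
    return [(float(time[s]), float(time[e])) for s, e in zip(starts, ends)]


def build_difference_curves(
    binned_spectra,
    posthoc: PosthocResult,
    duration: float = 1.2,
    binned_curves=None,
    pointwise_alpha: float = 0.05,
) -> DifferenceCurveSet:
    """Reconstruct per-pair difference curves and significance windows.

    For each bin pair the raw mean-difference curve is the inverse
    transform of the difference of bin-mean spectra (identical, by
    linearity, to the difference of the bin-mean time curves).  The
    wavelet-significant curve inverts the masked coefficient differences
    and its maximal nonzero runs are reported as time windows in
    seconds.  If ``binned_curves`` (6, 5, 256 time-domain) is given, a
    per-sample time-domain corroboration mask is built with the same
    omnibus + Scheffe scheme (unadjusted level) and applied to the raw
    difference curves.
    """
    spectra = _as_binned_array(binned_spectra)
    time = np.linspace(0.0, duration, spectra.shape[-1])
    bin_mean = spectra.mean(axis=1)
    diffs = np.array([bin_mean[b1 - 1] - bin_mean[b2 - 1] for b1, b2 in BIN_PAIRS])
    mean_diff = inverse_wavelet_batch(diffs)
    sig = inverse_wavelet_batch(np.where(posthoc.mask, diffs, 0.0))
    # an all-zero coefficient mask must reconstruct to an exact zero curve
    sig[~posthoc.mask.any(axis=1)] = 0.0
    windows = [_runs_above(sig[i], time, ZERO_TOL) for i in range(len(BIN_PAIRS))]

    pointwise = None
    if binned_curves is not None:
        curves = _as_binned_array(binned_curves)
        omnibus = pointwise_time_anova(curves, alpha=pointwise_alpha)
        k, n, _ = curves.shape
        crit = (k - 1) * sstats.f.isf(pointwise_alpha, k - 1, k * (n - 1))
        _, _, mse = _oneway_f(curves)
        cmean = curves.mean(axis=1)
        pointwise = np.zeros_like(mean_diff)
        with np.errstate(divide="ignore", invalid="ignore"):
            for row, (b1, b2) in enumerate(BIN_PAIRS):
                d = cmean[b1 - 1] - cmean[b2 - 1]
                stat = d**2 / (mse * (2.0 / n))
                stat = np.where(mse == 0, np.where(d == 0, 0.0, np.inf), stat)
                keep = omnibus.significant & (stat > crit)
                pointwise[row] = np.where(keep, d, 0.0)
    return DifferenceCurveSet(
        pairs=BIN_PAIRS,
        time=time,
        mean_difference=mean_diff,
        wavelet_significant=sig,
        windows=windows,
        pointwise_significant=pointwise,
    )


def pointwise_time_anova(binned_curves, alpha: float = 0.05) -> CoefficientAnovaResult:
    """Per-sample one-way ANOVA across bins in the time domain.

    Unadjusted corroboration of the wavelet-domain analysis: 256 tests
    at the nominal level on the raw curves.
    """
    arr = _as_binned_array(binned_curves)
    F, p, _ = _oneway_f(arr)
    return CoefficientAnovaResult(F=F, p=p, significant=p < alpha, alpha=alpha)


class WaveletBinAnova(BaseEstimator):
    """Estimator interface to the full wavelet-domain bin comparison.

    ``fit`` takes a (6, 5, 256) array of curves (or (30, 256) in
    chronological order), transforms them, runs the per-coefficient
    omnibus ANOVA, Scheffe post hoc with Bonferroni adjustment, and the
    time-domain corroboration, and reconstructs difference curves.

    Attributes
    ----------
    spectra_ : ndarray, (6, 5, 256)
    anova_ : CoefficientAnovaResult
    posthoc_ : PosthocResult
    pointwise_ : CoefficientAnovaResult
    difference_curves_ : DifferenceCurveSet
    """

    def __init__(self, alpha: float = 0.05, duration: float = 1.2):
        self.alpha = alpha
        self.duration = duration

    def fit(self, X, y=None) -> "WaveletBinAnova":
        curves = _as_binned_array(X)
        self.spectra_ = wavelet_transform_batch(curves)
        self.anova_ = per_coefficient_anova(self.spectra_, alpha=self.alpha)
        self.posthoc_ = scheffe_posthoc(self.spectra_, self.anova_, alpha=self.alpha)
        self.pointwise_ = pointwise_time_anova(curves, alpha=self.alpha)
        self.difference_curves_ = build_difference_curves(
            self.spectra_,
            self.posthoc_,
            duration=self.duration,
            binned_curves=curves,
            pointwise_alpha=self.alpha,
        )
        return self

    def significant_pairs(self) -> list[tuple[int, int]]:
        """Bin pairs with at least one post-hoc-significant coefficient."""
        return [
            pair
            for pair, row in zip(self.posthoc_.pairs, self.posthoc_.mask)
            if row.any()
        ]
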