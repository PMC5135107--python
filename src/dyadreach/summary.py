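"""End-of-movement summary statistics.

Two observations characterise the push-pull manipulation at the end of
the 1.2 s reach: the opposing torque is still being produced (paired
t-test, pusher vs puller torque at the final sample), and the endpoint
is biased — pushers overshoot the target, pullers undershoot (one-sample
t-tests on the signed endpoint error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .errors import CountError

__all__ = ["TTestResult", "opposing_torque_ttest", "endpoint_bias_ttest"]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    df: int
    mean: float


def opposing_torque_ttest(
    pusher_torques: np.ndarray, puller_torques: np.ndarray
) -> TTestResult:
    """Paired t-test on end-of-movement torque, pusher vs paired puller.

    Each element pairs the torque produced by the pushing partner with
    the torque of the pulling partner of the same dyad and block at the
    end of the reach; a large statistic means the opposing torque is
    systematically sustained through movement end.
    """
    pusher_torques = np.asarray(pusher_torques, dtype=float)
    puller_torques = np.asarray(puller_torques, dtype=float)
    if len(pusher_torques) != len(puller_torques) or len(pusher_torques) < 2:
        raise CountError("need >= 2 equal-length paired samples")
    res = sstats.ttest_rel(pusher_torques, puller_torques)
    return TTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=len(pusher_torques) - 1,
        mean=float(np.mean(pusher_torques - puller_torques)),
    )


def endpoint_bias_ttest(final_angles: np.ndarray, target: float = 30.0) -> TTestResult:
    """One-sample t-test of the signed endpoint error against zero.

    Positive bias = overshoot past the target, negative = undershoot.
    """
    final_angles = np.asarray(final_angles, dtype=float)
    if len(final_angles) < 2:
        raise CountError("need >= 2 endpoint samples")
    bias = final_angles - target
    res = sstats.ttest_1samp(bias, 0.0)
    return TTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=len(final_angles) - 1,
        mean=float(bias.mean()),
    )
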