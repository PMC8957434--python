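"""Inverse-variance pooling of study-level proportions.

Fixed-effect and DerSimonian-Laird (DL) random-effects pooling of
2-year recurrence-free survival proportions, with Cochran's Q, I^2 and
tau^2 heterogeneity statistics.  Pooling is available on the raw
proportion scale (within-study variance ``p(1-p)/n``, the default) or
on the logit scale (variance ``1/(n p (1-p))``, back-transformed CI).

The DL estimator: with fixed-effect weights ``w_i = 1/v_i``,

    Q    = sum w_i (p_i - p_fixed)^2
    tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)),  df = k - 1

and random-effects weights ``1/(v_i + tau2)``.  The 95% CI uses the
normal multiplier 1.96 on the pooling scale.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .synthetic import StudyRecord

__all__ = ["PoolMethod", "PoolScale", "PooledProportion", "pool_proportions", "heterogeneity"]

logger = logging.getLogger(__name__)

Z95 = 1.96


class PoolMethod(str, enum.Enum):
    FIXED = "fixed"
    RANDOM_DL = "random_DL"


class PoolScale(str, enum.Enum):
    RAW = "raw"
    LOGIT = "logit"


@dataclass(frozen=True)
class PooledProportion:
    """Pooled proportion with CI and heterogeneity statistics."""

    estimate: float
    ci_low: float
    ci_high: float
    q_stat: float
    df: int
    p_het: float
    i2: float  # proportion in [0, 1]; multiply by 100 to report as %
    tau2: float
    method: PoolMethod
    scale: PoolScale
    k: int
    n_total: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


def _effects_and_variances(
    studies: Sequence[StudyRecord], scale: PoolScale
) -> tuple[np.ndarray, np.ndarray]:
    if len(studies) == 0:
        raise ValueError("need at least one study to pool")
    p = np.array([s.rfs_24mo for s in studies], dtype=float)
    n = np.array([s.n_patients for s in studies], dtype=float)
    boundary = (p <= 0.0) | (p >= 1.0)
    if boundary.any():
        # 0.5/n continuity correction keeps both scales finite
        logger.warning(
            "continuity correction (0.5/n) applied to %d boundary proportion(s)",
            int(boundary.sum()),
        )
        p = np.where(p <= 0.0, 0.5 / n, p)
        p = np.where(p >= 1.0, 1.0 - 0.5 / n, p)
    if scale is PoolScale.RAW:
        return p, p * (1.0 - p) / n
    return logit(p), 1.0 / (n * p * (1.0 - p))


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float, int]:
    """Return (Q, tau2, df) from fixed-effect weights."""
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu) ** 2))
    df = len(y) - 1
    if df == 0:
        return q, 0.0, 0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return q, tau2, df


def heterogeneity(
    studies: Sequence[StudyRecord], scale: PoolScale | str = PoolScale.RAW
) -> dict[str, float]:
    """Cochran's Q, df, p-value, I^2 and DL tau^2 for one study set.

    A single study yields ``df=0, i2=0, tau2=0`` and ``p_het=1.0``.
    """
    scale = PoolScale(scale)
    y, v = _effects_and_variances(studies, scale)
    q, tau2, df = _dl_tau2(y, v)
    if df == 0:
        return {"q_stat": q, "df": 0, "p_het": 1.0, "i2": 0.0, "tau2": 0.0}
    p_het = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return {"q_stat": q, "df": df, "p_het": p_het, "i2": i2, "tau2": tau2}


def pool_proportions(
    studies: Sequence[StudyRecord],
    method: PoolMethod | str = PoolMethod.RANDOM_DL,
    scale: PoolScale | str = PoolScale.RAW,
) -> PooledProportion:
    """Pool study proportions by inverse-variance weighting.

    ``random_DL`` adds the DL ``tau2`` to each within-study variance;
    with ``tau2 == 0`` it coincides with the fixed-effect estimate.
    On the logit scale the estimate and CI are back-transformed to the
    proportion scale.
    """
    method = PoolMethod(method)
    scale = PoolScale(scale)
    y, v = _effects_and_variances(studies, scale)
    het = heterogeneity(studies, scale)
    tau2 = het["tau2"] if method is PoolMethod.RANDOM_DL else 0.0
    w = 1.0 / (v + tau2)
    est = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    lo, hi = est - Z95 * se, est + Z95 * se
    if scale is PoolScale.LOGIT:
        est, lo, hi = float(expit(est)), float(expit(lo)), float(expit(hi))
    else:
        lo, hi = max(0.0, lo), min(1.0, hi)
    return PooledProportion(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        q_stat=het["q_stat"],
        df=int(het["df"]),
        p_het=het["p_het"],
        i2=het["i2"],
        tau2=het["tau2"],
        method=method,
        scale=scale,
        k=len(studies),
        n_total=sum(s.n_patients for s in studies),
    )
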