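"""Survival / hazard-rate / transition-probability conversions.

Under a constant-hazard (declining-exponential) assumption, a cumulative
survival ``S`` observed at horizon ``T`` months implies a monthly hazard
``-ln(S)/T``, which converts to a per-cycle transition probability
``1 - exp(-rate * dt)``.  These three pure functions form an exact round
trip and are the bridge between the pooled 2-year recurrence-free
survival estimates and the Markov cohort model's monthly inputs.
"""

from __future__ import annotations

import math

__all__ = [
    "rate_from_survival",
    "prob_from_rate",
    "survival_from_prob",
    "monthly_prob_from_survival",
]


def rate_from_survival(survival: float, horizon_months: float) -> float:
    """Constant hazard rate (per month) implied by cumulative survival.

    Parameters
    ----------
    survival
        Cumulative survival proportion at the horizon, in (0, 1].
    horizon_months
        Horizon over which ``survival`` was observed, in months (> 0).

    Returns
    -------
    float
        Hazard rate per month, ``-ln(survival) / horizon_months``.
        Zero iff ``survival == 1``.
    """
    if not survival > 0.0:
        raise ValueError(f"survival must be positive, got {survival}")
    if survival > 1.0:
        raise ValueError(f"survival must be <= 1, got {survival}")
    if not horizon_months > 0.0:
        raise ValueError(f"horizon_months must be positive, got {horizon_months}")
    return -math.log(survival) / horizon_months


def prob_from_rate(rate: float, dt_months: float = 1.0) -> float:
    """Transition probability over ``dt_months`` for a constant hazard.

    ``1 - exp(-rate * dt)``; monotone increasing in both arguments.
    """
    if rate < 0.0:
        raise ValueError(f"rate must be non-negative, got {rate}")
    if not dt_months > 0.0:
        raise ValueError(f"dt_months must be positive, got {dt_months}")
    return -math.expm1(-rate * dt_months)


def survival_from_prob(monthly_prob: float, cycles: int) -> float:
    """Cumulative survival after ``cycles`` months at a fixed monthly probability."""
    if not 0.0 <= monthly_prob <= 1.0:
        raise ValueError(f"monthly_prob must be in [0, 1], got {monthly_prob}")
    if cycles < 1:
        raise ValueError(f"cycles must be >= 1, got {cycles}")
    return (1.0 - monthly_prob) ** cycles


def monthly_prob_from_survival(survival: float, horizon_months: float) -> float:
    """Monthly transition probability implied by cumulative survival at a horizon.

    Composition ``prob_from_rate(rate_from_survival(S, T), 1)``; e.g. a
    2-year recurrence-free survival of 0.752 implies a monthly
    progression probability of about 1.18%.
    """
    return prob_from_rate(rate_from_survival(survival, horizon_months), 1.0)
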