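"""Two-state absorbing Markov cohort model over monthly cycles.

States are progression-free survival (PFS) and an absorbing
progression-or-death (PD) state.  A cohort starts fully in PFS and
moves to PD with a constant monthly probability; follow-up costs and
utility accrue only in PFS (an optional variant lets PD accrue a
utility weight as well, so a PD utility can participate in sensitivity
analyses).  Costs and QALYs are discounted at an annual rate.

Reward-accrual and discounting conventions differ between decision-
modelling tools and are rarely printed, so both are explicit
configuration here:

* ``reward_timing``: ``end_of_cycle`` (occupancy after the cycle's
  transition, the default), ``start_of_cycle``, or ``half_cycle``
  (trapezoidal average of the two).
* ``discount_timing``: ``continuous_monthly`` (``(1+r)^(-t/12)``, the
  default) or ``annual_step`` (``(1+r)^(-floor(t/12))``).

``closed_form_pfs_months`` is the geometric-series closed form of the
default convention's accumulation, kept as an independent oracle for
the trace recursion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "RewardTiming",
    "DiscountTiming",
    "MarkovSpec",
    "StrategySpec",
    "CohortTrace",
    "StrategyOutcome",
    "discount_factor",
    "run_cohort",
    "closed_form_pfs_months",
]


class RewardTiming(str, enum.Enum):
    END_OF_CYCLE = "end_of_cycle"
    START_OF_CYCLE = "start_of_cycle"
    HALF_CYCLE = "half_cycle"


class DiscountTiming(str, enum.Enum):
    CONTINUOUS_MONTHLY = "continuous_monthly"
    ANNUAL_STEP = "annual_step"


@dataclass(frozen=True)
class MarkovSpec:
    """Structure of the cohort model: horizon, discounting, conventions."""

    horizon_cycles: int = 24
    cycle_length_months: float = 1.0
    annual_discount: float = 0.05
    reward_timing: RewardTiming = RewardTiming.END_OF_CYCLE
    discount_timing: DiscountTiming = DiscountTiming.CONTINUOUS_MONTHLY
    pd_accrues_utility: bool = False

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ValueError(f"horizon_cycles must be >= 1, got {self.horizon_cycles}")
        if not 0.0 <= self.annual_discount <= 1.0:
            raise ValueError(
                f"annual_discount must be in [0, 1], got {self.annual_discount}"
            )
        object.__setattr__(self, "reward_timing", RewardTiming(self.reward_timing))
        object.__setattr__(self, "discount_timing", DiscountTiming(self.discount_timing))

    def with_(self, **kw) -> "MarkovSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class StrategySpec:
    """One surveillance strategy: monthly progression probability, cost, utilities.

    Utilities are annual quality weights in [0, 1]; a month in PFS at
    utility u contributes u/12 QALYs before discounting.  ``utility_pd``
    is only accrued when the model's ``pd_accrues_utility`` flag is set.
    """

    name: str
    monthly_prob_pfs_to_pd: float
    monthly_cost: float
    utility_pfs: float = 0.76
    utility_pd: float = 0.68

    def __post_init__(self) -> None:
        if not 0.0 <= self.monthly_prob_pfs_to_pd <= 1.0:
            raise ValueError(
                "monthly_prob_pfs_to_pd must be in [0, 1], "
                f"got {self.monthly_prob_pfs_to_pd}"
            )
        if self.monthly_cost < 0.0:
            raise ValueError(f"monthly_cost must be >= 0, got {self.monthly_cost}")
        for label, u in (("utility_pfs", self.utility_pfs), ("utility_pd", self.utility_pd)):
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {u}")

    def with_(self, **kw) -> "StrategySpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy and discounted reward accrual."""

    cycle: np.ndarray
    occupancy_pfs: np.ndarray
    occupancy_pd: np.ndarray
    discount: np.ndarray
    cost: np.ndarray  # discounted cost accrued in cycle t (0 at t=0)
    qaly: np.ndarray  # discounted QALY accrued in cycle t

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "occupancy_pfs": self.occupancy_pfs,
                "occupancy_pd": self.occupancy_pd,
                "discount": self.discount,
                "cost": self.cost,
                "qaly": self.qaly,
            }
        )


@dataclass(frozen=True)
class StrategyOutcome:
    """Totals of one cohort run: discounted cost, QALYs, PFS-months."""

    name: str
    discounted_cost: float
    discounted_qaly: float
    discounted_pfs_months: float


def discount_factor(cycle_index: int, spec: MarkovSpec) -> float:
    """Discount factor applied at cycle ``cycle_index`` (1.0 at t=0)."""
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be >= 0, got {cycle_index}")
    r = 1.0 + spec.annual_discount
    months = cycle_index * spec.cycle_length_months
    if spec.discount_timing is DiscountTiming.CONTINUOUS_MONTHLY:
        return float(r ** (-months / 12.0))
    return float(r ** (-np.floor(months / 12.0)))


def _discount_vector(spec: MarkovSpec) -> np.ndarray:
    t = np.arange(spec.horizon_cycles + 1)
    r = 1.0 + spec.annual_discount
    months = t * spec.cycle_length_months
    if spec.discount_timing is DiscountTiming.CONTINUOUS_MONTHLY:
        return r ** (-months / 12.0)
    return r ** (-np.floor(months / 12.0))


def run_cohort(
    model: MarkovSpec, strategy: StrategySpec
) -> tuple[CohortTrace, StrategyOutcome]:
    """Propagate the cohort and accrue discounted rewards.

    Occupancy recursion: ``S_PFS(t) = S_PFS(t-1) * (1 - p)`` with the
    whole cohort in PFS at t=0.  Per-cycle reward weights follow the
    model's ``reward_timing``; costs accrue in PFS only.
    """
    n = model.horizon_cycles
    p = strategy.monthly_prob_pfs_to_pd
    t = np.arange(n + 1)
    occ_pfs = (1.0 - p) ** t
    occ_pd = 1.0 - occ_pfs
    disc = _discount_vector(model)

    # discounted state-months credited to each cycle 1..N
    if model.reward_timing is RewardTiming.END_OF_CYCLE:
        w_pfs = occ_pfs[1:] * disc[1:]
        w_pd = occ_pd[1:] * disc[1:]
    elif model.reward_timing is RewardTiming.START_OF_CYCLE:
        w_pfs = occ_pfs[:-1] * disc[:-1]
        w_pd = occ_pd[:-1] * disc[:-1]
    else:  # half-cycle: trapezoid of the two discounted occupancies
        w_pfs = 0.5 * (occ_pfs[:-1] * disc[:-1] + occ_pfs[1:] * disc[1:])
        w_pd = 0.5 * (occ_pd[:-1] * disc[:-1] + occ_pd[1:] * disc[1:])
    w_pfs = w_pfs * model.cycle_length_months
    w_pd = w_pd * model.cycle_length_months

    cost_per_cycle = np.concatenate([[0.0], w_pfs * strategy.monthly_cost])
    qaly_per_cycle = np.concatenate([[0.0], w_pfs * strategy.utility_pfs / 12.0])
    if model.pd_accrues_utility:
        qaly_per_cycle[1:] += w_pd * strategy.utility_pd / 12.0

    trace = CohortTrace(
        cycle=t,
        occupancy_pfs=occ_pfs,
        occupancy_pd=occ_pd,
        discount=disc,
        cost=cost_per_cycle,
        qaly=qaly_per_cycle,
    )
    outcome = StrategyOutcome(
        name=strategy.name,
        discounted_cost=float(cost_per_cycle.sum()),
        discounted_qaly=float(qaly_per_cycle.sum()),
        discounted_pfs_months=float(w_pfs.sum()),
    )
    return trace, outcome


def closed_form_pfs_months(
    p: float, monthly_discount: float, cycles: int
) -> float:
    """Geometric closed form of end-of-cycle discounted PFS-months.

    ``sum_{t=1..N} ((1-p) * d)^t = r (1 - r^N) / (1 - r)`` with
    ``r = (1-p) * d``; falls back to the direct sum when ``r`` is at or
    near 1.  Independent oracle for :func:`run_cohort` under the default
    convention.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    r = (1.0 - p) * monthly_discount
    if abs(1.0 - r) < 1e-12:
        return float(np.sum(r ** np.arange(1, cycles + 1)))
    return float(r * (1.0 - r**cycles) / (1.0 - r))
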