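"""Cost-effectiveness comparison of two strategy outcomes.

Incremental cost and effect, the incremental cost-effectiveness ratio
(ICER = dC/dE), dominance classification, and net monetary benefit
(NMB = WTP * QALY - cost) at a willingness-to-pay threshold.  The
NMB-preferred strategy coincides with the ICER-below-threshold rule
whenever the incremental effect is positive.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .markov import StrategyOutcome

__all__ = ["Dominance", "CEAResult", "WTPRule", "icer", "nmb", "decide"]

#: 2020 Chinese GDP per capita, the willingness-to-pay threshold ($/QALY).
DEFAULT_WTP = 10888.0


class Dominance(str, enum.Enum):
    ICER_DEFINED = "icer_defined"
    COMPARATOR_DOMINATES = "comparator_dominates"
    COMPARATOR_DOMINATED = "comparator_dominated"
    EQUAL_EFFECT = "equal_effect"


@dataclass(frozen=True)
class WTPRule:
    wtp: float = DEFAULT_WTP

    def __post_init__(self) -> None:
        if self.wtp < 0.0:
            raise ValueError(f"wtp must be >= 0, got {self.wtp}")


@dataclass(frozen=True)
class CEAResult:
    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float  # NaN unless classification is icer_defined
    classification: Dominance


def icer(comparator: StrategyOutcome, reference: StrategyOutcome) -> CEAResult:
    """Incremental comparison of ``comparator`` against ``reference``.

    Deltas are comparator minus reference.  A comparator that is at
    least as cheap and strictly more effective dominates; the mirrored
    case is dominated; equal effects yield no ICER.
    """
    d_cost = comparator.discounted_cost - reference.discounted_cost
    d_eff = comparator.discounted_qaly - reference.discounted_qaly
    if d_eff == 0.0:
        cls = Dominance.EQUAL_EFFECT
        ratio = math.nan
    elif d_eff > 0.0 and d_cost <= 0.0:
        cls = Dominance.COMPARATOR_DOMINATES
        ratio = math.nan
    elif d_eff < 0.0 and d_cost >= 0.0:
        cls = Dominance.COMPARATOR_DOMINATED
        ratio = math.nan
    else:
        cls = Dominance.ICER_DEFINED
        ratio = d_cost / d_eff
    return CEAResult(
        reference=reference.name,
        comparator=comparator.name,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=ratio,
        classification=cls,
    )


def nmb(outcome: StrategyOutcome, rule: WTPRule) -> float:
    """Net monetary benefit: ``wtp * discounted QALYs - discounted cost``."""
    return rule.wtp * outcome.discounted_qaly - outcome.discounted_cost


def decide(
    comparator: StrategyOutcome, reference: StrategyOutcome, rule: WTPRule
) -> str:
    """Name of the NMB-preferred strategy.

    NMB ties resolve to the lower-cost strategy; a full tie resolves to
    the reference.
    """
    nmb_c, nmb_r = nmb(comparator, rule), nmb(reference, rule)
    if nmb_c > nmb_r:
        return comparator.name
    if nmb_c < nmb_r:
        return reference.name
    if comparator.discounted_cost < reference.discounted_cost:
        return comparator.name
    return reference.name
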