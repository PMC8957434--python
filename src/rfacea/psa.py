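"""Probabilistic sensitivity analysis and acceptability curves.

Parameter uncertainty is represented by moment-matched distributions:
beta for probabilities and utilities, gamma for costs.  The mean is the
base value; the standard deviation comes from the published range under
one of two readings:

* ``ci95`` (default): the range is a 95% plausible interval, so
  ``sd = (high - low) / 3.92``;
* ``minmax``: the range is a uniform support, ``sd = (high - low) / sqrt(12)``.

Each Monte Carlo draw samples every assigned parameter independently,
rebuilds both strategies, runs the cohort model, and records the
outcomes; the acceptability curve is the fraction of draws in which
each strategy has the higher net monetary benefit at each
willingness-to-pay value (ties resolved exactly as the base-case
decision rule resolves them).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dsa import ParamDistribution, ParamSpec, Scenario
from .markov import StrategyOutcome
from .metrics import WTPRule, decide

__all__ = [
    "RangeSemantics",
    "DistributionAssignment",
    "PSASample",
    "CEACPoint",
    "beta_from_mean_range",
    "gamma_from_mean_range",
    "assign_distributions",
    "run_psa",
    "ceac",
]


class RangeSemantics(str, enum.Enum):
    CI95 = "ci95"
    MINMAX = "minmax"


def _sd_from_range(low: float, high: float, semantics: RangeSemantics) -> float:
    if not low < high:
        raise ValueError(f"need low < high, got {low}, {high}")
    if RangeSemantics(semantics) is RangeSemantics.CI95:
        return (high - low) / 3.92
    return (high - low) / math.sqrt(12.0)


def beta_from_mean_range(
    mean: float,
    low: float,
    high: float,
    range_semantics: RangeSemantics | str = RangeSemantics.CI95,
) -> tuple[float, float]:
    """Method-of-moments beta shape parameters ``(alpha, beta)``.

    ``alpha + beta = mean (1 - mean) / sd^2 - 1``; the fitted
    distribution reproduces the requested mean and sd exactly.  Raises
    if the moments are infeasible for a beta (``sd^2 >= mean(1-mean)``).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    sd = _sd_from_range(low, high, RangeSemantics(range_semantics))
    if sd**2 >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta moments: sd^2={sd**2:.6g} >= "
            f"mean(1-mean)={mean * (1 - mean):.6g}"
        )
    total = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * total, (1.0 - mean) * total


def gamma_from_mean_range(
    mean: float,
    low: float,
    high: float,
    range_semantics: RangeSemantics | str = RangeSemantics.CI95,
) -> tuple[float, float]:
    """Method-of-moments gamma ``(shape, scale)``: shape=(mean/sd)^2, scale=sd^2/mean."""
    if not mean > 0.0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    sd = _sd_from_range(low, high, RangeSemantics(range_semantics))
    return (mean / sd) ** 2, sd**2 / mean


@dataclass(frozen=True)
class DistributionAssignment:
    """A parameter together with its fitted sampling distribution."""

    param: ParamSpec
    family: ParamDistribution
    mean: float
    sd: float
    fitted: tuple[float, float]  # (alpha, beta) or (shape, scale); (base, 0) if fixed

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family is ParamDistribution.BETA:
            return rng.beta(*self.fitted, size=size)
        if self.family is ParamDistribution.GAMMA:
            return rng.gamma(self.fitted[0], self.fitted[1], size=size)
        return np.full(size, self.param.base)


def assign_distributions(
    params: Sequence[ParamSpec],
    range_semantics: RangeSemantics | str = RangeSemantics.CI95,
) -> list[DistributionAssignment]:
    """Fit each parameter's declared family to its base value and range.

    ``fixed`` parameters stay degenerate at their base value.  Fails
    before any sampling if a beta's moments are infeasible.
    """
    semantics = RangeSemantics(range_semantics)
    out = []
    for p in params:
        if p.distribution is ParamDistribution.BETA:
            fitted = beta_from_mean_range(p.base, p.low, p.high, semantics)
            sd = _sd_from_range(p.low, p.high, semantics)
        elif p.distribution is ParamDistribution.GAMMA:
            fitted = gamma_from_mean_range(p.base, p.low, p.high, semantics)
            sd = _sd_from_range(p.low, p.high, semantics)
        else:
            fitted, sd = (p.base, 0.0), 0.0
        out.append(
            DistributionAssignment(
                param=p, family=p.distribution, mean=p.base, sd=sd, fitted=fitted
            )
        )
    return out


@dataclass(frozen=True)
class PSASample:
    draw_index: int
    params: dict[str, float]
    outcome_two_three: StrategyOutcome
    outcome_three_four: StrategyOutcome


def run_psa(
    scenario: Scenario,
    assignments: Sequence[DistributionAssignment],
    n_draws: int,
    seed: int,
) -> list[PSASample]:
    """Monte Carlo resampling of the full model.

    One root seed; each parameter gets its own substream (spawned in
    declaration order), so adding a parameter at the end does not
    perturb earlier parameters' draws.  Reproducible for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    streams = np.random.SeedSequence(seed).spawn(len(assignments))
    draws = {
        a.param.name: a.sample(np.random.default_rng(s), n_draws)
        for a, s in zip(assignments, streams)
    }
    samples = []
    for i in range(n_draws):
        overrides: dict[str, float] = {}
        values: dict[str, float] = {}
        for a in assignments:
            v = float(draws[a.param.name][i])
            values[a.param.name] = v
            for path in a.param.targets:
                overrides[path] = v
        o23, o34 = scenario.with_overrides(overrides).outcomes()
        samples.append(PSASample(i, values, o23, o34))
    return samples


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_2_3_preferred: float
    prob_3_4_preferred: float


def ceac(
    samples: Sequence[PSASample], wtp_grid: Sequence[float]
) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At each WTP, the probability that each strategy is NMB-preferred;
    the two probabilities partition 1 (ties go to the lower-cost
    strategy, and then to the reference, exactly as in the base-case
    decision rule).
    """
    if not samples or not len(wtp_grid):
        raise ValueError("need non-empty samples and WTP grid")
    q23 = np.array([s.outcome_two_three.discounted_qaly for s in samples])
    c23 = np.array([s.outcome_two_three.discounted_cost for s in samples])
    q34 = np.array([s.outcome_three_four.discounted_qaly for s in samples])
    c34 = np.array([s.outcome_three_four.discounted_cost for s in samples])
    points = []
    for w in wtp_grid:
        nmb23 = w * q23 - c23
        nmb34 = w * q34 - c34
        pref23 = (nmb23 > nmb34) | ((nmb23 == nmb34) & (c23 < c34))
        p = float(pref23.mean())
        points.append(CEACPoint(float(w), p, 1.0 - p))
    return points


def decide_per_draw(samples: Sequence[PSASample], rule: WTPRule) -> list[str]:
    """Base-case decision rule applied draw by draw (CEAC consistency check)."""
    return [decide(s.outcome_two_three, s.outcome_three_four, rule) for s in samples]
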