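"""Deterministic sensitivity analyses: one-way (tornado), two-way, threshold.

A :class:`Scenario` bundles the model structure, the two strategies
(the 2-to-3-month comparator and the 3-to-4-month reference) and the
willingness-to-pay rule.  Parameters are described by :class:`ParamSpec`
with dotted target paths into the scenario (e.g.
``two_three.monthly_cost``); a parameter may set several targets at
once, which is how a shared utility applies to both strategies.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .markov import MarkovSpec, StrategySpec, StrategyOutcome, run_cohort
from .metrics import WTPRule, decide, nmb

__all__ = [
    "ParamDistribution",
    "ParamSpec",
    "Scenario",
    "TornadoEntry",
    "NMBTarget",
    "one_way",
    "two_way",
    "threshold",
]


class ParamDistribution(str, enum.Enum):
    BETA = "beta"
    GAMMA = "gamma"
    FIXED = "fixed"


class NMBTarget(str, enum.Enum):
    STRATEGY_2_3 = "strategy_2_3"
    INCREMENTAL = "incremental"


@dataclass(frozen=True)
class ParamSpec:
    """One model parameter: base value, range, distribution family, targets."""

    name: str
    base: float
    low: float
    high: float
    distribution: ParamDistribution = ParamDistribution.FIXED
    targets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: need low <= base <= high, "
                f"got {self.low}, {self.base}, {self.high}"
            )
        object.__setattr__(self, "distribution", ParamDistribution(self.distribution))
        object.__setattr__(self, "targets", tuple(self.targets))


@dataclass(frozen=True)
class Scenario:
    """Model + both strategies + WTP rule; the unit the analyses re-run."""

    model: MarkovSpec
    two_three: StrategySpec
    three_four: StrategySpec
    rule: WTPRule

    def with_overrides(self, overrides: dict[str, float]) -> "Scenario":
        """Copy with dotted-path fields replaced, e.g. ``{"rule.wtp": 5e3}``."""
        parts: dict[str, dict[str, float]] = {}
        for path, value in overrides.items():
            try:
                root, field = path.split(".")
            except ValueError as exc:
                raise KeyError(f"override path {path!r} is not 'root.field'") from exc
            if root not in ("model", "two_three", "three_four", "rule"):
                raise KeyError(f"unknown override root {root!r} in {path!r}")
            if not hasattr(getattr(self, root), field):
                raise KeyError(f"{root} has no field {field!r}")
            parts.setdefault(root, {})[field] = value
        return replace(
            self,
            **{root: replace(getattr(self, root), **kw) for root, kw in parts.items()},
        )

    def outcomes(self) -> tuple[StrategyOutcome, StrategyOutcome]:
        _, o23 = run_cohort(self.model, self.two_three)
        _, o34 = run_cohort(self.model, self.three_four)
        return o23, o34

    def nmb_two_three(self) -> float:
        o23, _ = self.outcomes()
        return nmb(o23, self.rule)

    def incremental_nmb(self) -> float:
        o23, o34 = self.outcomes()
        return nmb(o23, self.rule) - nmb(o34, self.rule)

    def preferred(self) -> str:
        o23, o34 = self.outcomes()
        return decide(o23, o34, self.rule)


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    nmb_at_low: float
    nmb_at_high: float
    swing: float


def _nmb_fn(scenario: Scenario, nmb_target: NMBTarget) -> Callable[[dict], float]:
    if NMBTarget(nmb_target) is NMBTarget.STRATEGY_2_3:
        return lambda ov: scenario.with_overrides(ov).nmb_two_three()
    return lambda ov: scenario.with_overrides(ov).incremental_nmb()


def _overrides(param: ParamSpec, value: float) -> dict[str, float]:
    if not param.targets:
        raise KeyError(f"parameter {param.name!r} has no target paths")
    return {path: value for path in param.targets}


def one_way(
    params: Sequence[ParamSpec],
    scenario: Scenario,
    nmb_target: NMBTarget | str = NMBTarget.STRATEGY_2_3,
) -> list[TornadoEntry]:
    """Tornado analysis: NMB at each parameter's low and high, others at base.

    Returns entries sorted by swing, widest first.
    """
    f = _nmb_fn(scenario, NMBTarget(nmb_target))
    entries = []
    for p in params:
        lo = f(_overrides(p, p.low))
        hi = f(_overrides(p, p.high))
        entries.append(TornadoEntry(p.name, lo, hi, abs(hi - lo)))
    return sorted(entries, key=lambda e: -e.swing)


def two_way(
    param_a: ParamSpec,
    param_b: ParamSpec,
    grid_points: int,
    scenario: Scenario,
) -> pd.DataFrame:
    """Preferred-strategy label on a Cartesian grid over two ranges.

    Columns ``a_value, b_value, preferred``; rows in row-major order
    over ``param_a``'s grid then ``param_b``'s.
    """
    if param_a.name == param_b.name:
        raise ValueError("two_way needs two distinct parameters")
    if grid_points < 2:
        raise ValueError(f"grid_points must be >= 2, got {grid_points}")
    a_grid = np.linspace(param_a.low, param_a.high, grid_points)
    b_grid = np.linspace(param_b.low, param_b.high, grid_points)
    rows = []
    for a in a_grid:
        for b in b_grid:
            ov = {**_overrides(param_a, float(a)), **_overrides(param_b, float(b))}
            rows.append((float(a), float(b), scenario.with_overrides(ov).preferred()))
    return pd.DataFrame(rows, columns=["a_value", "b_value", "preferred"])


def threshold(
    param: ParamSpec,
    scenario: Scenario,
    tol: float | None = None,
    scan_points: int = 401,
) -> float | list[float] | None:
    """Parameter value where the NMB-preferred strategy flips, if any.

    Scans the incremental NMB over ``[low, high]``, then refines each
    sign change by Brent bisection to ``tol`` (default 1e-6 of the
    range).  Returns ``None`` with no sign change, a float with exactly
    one, and — with a warning — a list when the NMB difference is
    non-monotone and crosses several times.
    """
    span = param.high - param.low
    if span <= 0.0:
        return None
    if tol is None:
        tol = 1e-6 * span
    if not tol > 0.0:
        raise ValueError(f"tol must be positive, got {tol}")

    def f(x: float) -> float:
        return scenario.with_overrides(_overrides(param, x)).incremental_nmb()

    grid = np.linspace(param.low, param.high, scan_points)
    values = np.array([f(x) for x in grid])
    sign = np.sign(values)
    crossings = []
    for i in range(len(grid) - 1):
        if sign[i] == 0.0:
            crossings.append(float(grid[i]))
        elif sign[i] * sign[i + 1] < 0.0:
            crossings.append(float(brentq(f, grid[i], grid[i + 1], xtol=tol)))
    if sign[-1] == 0.0:
        crossings.append(float(grid[-1]))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(
            f"NMB difference is non-monotone over {param.name}'s range; "
            f"{len(crossings)} crossings found",
            stacklevel=2,
        )
        return crossings
    return crossings[0]
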