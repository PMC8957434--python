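"""Analysis configuration: parameter table, validation, scenario building.

The configuration mirrors the published parameter table: pooled 2-year
recurrence-free survivals (or a study table to pool them from), monthly
follow-up costs, health-state utilities, the annual discount rate, the
willingness-to-pay threshold, sensitivity ranges (50%-200% of the
benchmark for probabilities and costs, published ranges for utilities),
and the Monte Carlo settings.  Costs are US dollars; the RMB conversion
constant is carried as provenance metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import yaml

from .dsa import ParamDistribution, ParamSpec, Scenario
from .markov import DiscountTiming, MarkovSpec, RewardTiming, StrategySpec
from .metrics import WTPRule
from .transitions import monthly_prob_from_survival

__all__ = ["AnalysisConfig", "validate_config", "build_scenario", "default_param_specs"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs of the full analysis; defaults reproduce the base case."""

    # evidence: either a study table to pool, or pooled survivals directly
    study_table: str | None = None
    pooled_survival_two_three: float | None = 0.752
    pooled_survival_three_four: float | None = 0.543
    horizon_months: int = 24

    # parameter table
    monthly_cost_two_three: float = 117.16
    monthly_cost_three_four: float = 78.10
    utility_pfs: float = 0.76
    utility_pfs_range: tuple[float, float] = (0.61, 0.91)
    utility_pd: float = 0.68
    utility_pd_range: tuple[float, float] = (0.54, 0.82)
    annual_discount: float = 0.05
    discount_range: tuple[float, float] = (0.0, 0.05)
    wtp: float = 10888.0

    # conventions
    use_printed_probs: bool = True  # round derived monthly probs to 4 d.p.
    reward_timing: str = RewardTiming.END_OF_CYCLE.value
    discount_timing: str = DiscountTiming.CONTINUOUS_MONTHLY.value
    pd_accrues_utility: bool = False

    # sensitivity settings
    sa_low_factor: float = 0.5
    sa_high_factor: float = 2.0
    range_semantics: str = "ci95"
    psa_n: int = 10_000
    psa_seed: int = 42
    wtp_grid_max: float = 20_000.0
    wtp_grid_step: float = 100.0

    # two-way grid resolution
    two_way_grid_points: int = 11

    # provenance metadata (not used in computation)
    currency: str = "USD"
    rmb_per_usd: float = 6.56

    def __post_init__(self) -> None:
        object.__setattr__(self, "utility_pfs_range", tuple(self.utility_pfs_range))
        object.__setattr__(self, "utility_pd_range", tuple(self.utility_pd_range))
        object.__setattr__(self, "discount_range", tuple(self.discount_range))

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AnalysisConfig":
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise IOError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def validate_config(config: AnalysisConfig) -> list[str]:
    """Return a list of violations; empty iff the configuration is valid."""
    v: list[str] = []
    has_table = config.study_table is not None
    has_pooled = (
        config.pooled_survival_two_three is not None
        and config.pooled_survival_three_four is not None
    )
    if not has_table and not has_pooled:
        v.append("either study_table or both pooled survivals must be provided")
    if has_table and not Path(config.study_table).exists():
        v.append(f"study_table file does not exist: {config.study_table}")
    for name in ("pooled_survival_two_three", "pooled_survival_three_four"):
        s = getattr(config, name)
        if s is not None and not 0.0 < s <= 1.0:
            v.append(f"{name} must be in (0, 1], got {s}")
    if config.horizon_months < 1:
        v.append(f"horizon_months must be >= 1, got {config.horizon_months}")
    for name in ("monthly_cost_two_three", "monthly_cost_three_four"):
        if getattr(config, name) < 0.0:
            v.append(f"{name} must be >= 0")
    for name in ("utility_pfs", "utility_pd"):
        u = getattr(config, name)
        if not 0.0 <= u <= 1.0:
            v.append(f"{name} must be in [0, 1], got {u}")
        lo, hi = getattr(config, f"{name}_range")
        if lo > hi:
            v.append(f"{name}_range low {lo} exceeds high {hi}")
        elif not lo <= u <= hi:
            v.append(f"{name}={u} outside its range [{lo}, {hi}]")
    if not 0.0 <= config.annual_discount <= 1.0:
        v.append(f"annual_discount must be in [0, 1], got {config.annual_discount}")
    lo, hi = config.discount_range
    if lo > hi:
        v.append(f"discount_range low {lo} exceeds high {hi}")
    if config.wtp < 0.0:
        v.append(f"wtp must be >= 0, got {config.wtp}")
    if not 0.0 < config.sa_low_factor <= 1.0 <= config.sa_high_factor:
        v.append("need sa_low_factor <= 1 <= sa_high_factor, both positive")
    if config.range_semantics not in ("ci95", "minmax"):
        v.append(f"range_semantics must be ci95 or minmax, got {config.range_semantics}")
    if config.psa_n < 1:
        v.append(f"psa_n must be >= 1, got {config.psa_n}")
    try:
        RewardTiming(config.reward_timing)
    except ValueError:
        v.append(f"unknown reward_timing {config.reward_timing!r}")
    try:
        DiscountTiming(config.discount_timing)
    except ValueError:
        v.append(f"unknown discount_timing {config.discount_timing!r}")
    return v


def derive_monthly_probs(
    config: AnalysisConfig,
    survival_two_three: float | None = None,
    survival_three_four: float | None = None,
) -> dict[str, float]:
    """Monthly transition probabilities from the pooled survivals.

    Full-precision constant-hazard conversion, plus the values actually
    fed downstream (rounded to 4 decimals — i.e. the printed 1.18% /
    2.51% — unless ``use_printed_probs`` is off).
    """
    s23 = survival_two_three
    if s23 is None:
        s23 = config.pooled_survival_two_three
    s34 = survival_three_four
    if s34 is None:
        s34 = config.pooled_survival_three_four
    p23 = monthly_prob_from_survival(s23, config.horizon_months)
    p34 = monthly_prob_from_survival(s34, config.horizon_months)
    used23, used34 = (round(p23, 4), round(p34, 4)) if config.use_printed_probs else (p23, p34)
    return {
        "survival_two_three": s23,
        "survival_three_four": s34,
        "prob_two_three_full": p23,
        "prob_three_four_full": p34,
        "prob_two_three": used23,
        "prob_three_four": used34,
    }


def build_scenario(
    config: AnalysisConfig,
    prob_two_three: float | None = None,
    prob_three_four: float | None = None,
) -> Scenario:
    """Assemble the base-case scenario from the configuration."""
    if prob_two_three is None or prob_three_four is None:
        probs = derive_monthly_probs(config)
        prob_two_three = probs["prob_two_three"]
        prob_three_four = probs["prob_three_four"]
    model = MarkovSpec(
        horizon_cycles=config.horizon_months,
        annual_discount=config.annual_discount,
        reward_timing=RewardTiming(config.reward_timing),
        discount_timing=DiscountTiming(config.discount_timing),
        pd_accrues_utility=config.pd_accrues_utility,
    )
    two_three = StrategySpec(
        name="two_three_month",
        monthly_prob_pfs_to_pd=prob_two_three,
        monthly_cost=config.monthly_cost_two_three,
        utility_pfs=config.utility_pfs,
        utility_pd=config.utility_pd,
    )
    three_four = StrategySpec(
        name="three_four_month",
        monthly_prob_pfs_to_pd=prob_three_four,
        monthly_cost=config.monthly_cost_three_four,
        utility_pfs=config.utility_pfs,
        utility_pd=config.utility_pd,
    )
    return Scenario(model, two_three, three_four, WTPRule(config.wtp))


def default_param_specs(
    config: AnalysisConfig, scenario: Scenario
) -> list[ParamSpec]:
    """Parameter table for the sensitivity analyses.

    Probabilities and costs range over 50%-200% of the benchmark value;
    utilities use their published ranges; the discount rate varies from
    0 to its base value and stays fixed in the PSA.
    """
    lo_f, hi_f = config.sa_low_factor, config.sa_high_factor
    p23 = scenario.two_three.monthly_prob_pfs_to_pd
    p34 = scenario.three_four.monthly_prob_pfs_to_pd
    return [
        ParamSpec(
            "p_two_three", p23, lo_f * p23, hi_f * p23,
            ParamDistribution.BETA, ("two_three.monthly_prob_pfs_to_pd",),
        ),
        ParamSpec(
            "p_three_four", p34, lo_f * p34, hi_f * p34,
            ParamDistribution.BETA, ("three_four.monthly_prob_pfs_to_pd",),
        ),
        ParamSpec(
            "cost_two_three",
            config.monthly_cost_two_three,
            lo_f * config.monthly_cost_two_three,
            hi_f * config.monthly_cost_two_three,
            ParamDistribution.GAMMA, ("two_three.monthly_cost",),
        ),
        ParamSpec(
            "cost_three_four",
            config.monthly_cost_three_four,
            lo_f * config.monthly_cost_three_four,
            hi_f * config.monthly_cost_three_four,
            ParamDistribution.GAMMA, ("three_four.monthly_cost",),
        ),
        ParamSpec(
            "utility_pfs", config.utility_pfs, *config.utility_pfs_range,
            ParamDistribution.BETA,
            ("two_three.utility_pfs", "three_four.utility_pfs"),
        ),
        ParamSpec(
            "utility_pd", config.utility_pd, *config.utility_pd_range,
            ParamDistribution.BETA,
            ("two_three.utility_pd", "three_four.utility_pd"),
        ),
        ParamSpec(
            "discount_rate", config.annual_discount, *config.discount_range,
            ParamDistribution.FIXED, ("model.annual_discount",),
        ),
    ]
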