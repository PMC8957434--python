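"""End-to-end orchestration: study table -> pooled survivals -> monthly
probabilities -> base-case cohort runs -> ICER/NMB -> deterministic and
probabilistic sensitivity analyses.

``run_full_analysis`` returns a report bundle (plain dict of numbers
and DataFrames) and can persist it as CSV/JSON; every intermediate —
pooled estimates, hazard rates, transition probabilities, the implied
discounted PFS-months under each reward/discount convention — is logged
and kept in the bundle, because the implied-months figure is what
exposes convention mismatches between modelling tools.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import psa as psa_mod
from .config import (
    AnalysisConfig,
    build_scenario,
    default_param_specs,
    derive_monthly_probs,
    validate_config,
)
from .dsa import NMBTarget, one_way, threshold, two_way
from .markov import DiscountTiming, RewardTiming, run_cohort
from .metrics import icer, nmb
from .pooling import pool_proportions
from .synthetic import Group, read_studies_csv
from .transitions import rate_from_survival

__all__ = ["run_full_analysis", "base_case", "implied_months_by_convention"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _pool_from_table(config: AnalysisConfig) -> dict[str, Any]:
    studies = read_studies_csv(config.study_table)
    out = {}
    for group, key in ((Group.TWO_THREE, "two_three"), (Group.THREE_FOUR, "three_four")):
        subset = [s for s in studies if s.group is group]
        if not subset:
            raise PipelineError("pooling", f"study table has no rows for {group.value}")
        pooled = pool_proportions(subset)
        logger.info(
            "pooled %s: %.4f (95%% CI %.4f-%.4f), I^2=%.1f%%, tau2=%.5f, k=%d, n=%d",
            key, pooled.estimate, pooled.ci_low, pooled.ci_high,
            100 * pooled.i2, pooled.tau2, pooled.k, pooled.n_total,
        )
        out[key] = pooled
    return out


def implied_months_by_convention(
    config: AnalysisConfig, probs: dict[str, float] | None = None
) -> pd.DataFrame:
    """Discounted PFS-months of both strategies under every convention.

    The comparable figure implied by a published cost row is simply
    cost divided by the monthly cost, so this table is the diagnostic
    for identifying which convention another tool used.
    """
    if probs is None:
        probs = derive_monthly_probs(config)
    rows = []
    for rt in RewardTiming:
        for dt in DiscountTiming:
            scen = build_scenario(
                config.with_(reward_timing=rt.value, discount_timing=dt.value),
                probs["prob_two_three"],
                probs["prob_three_four"],
            )
            o23, o34 = scen.outcomes()
            rows.append(
                (rt.value, dt.value,
                 o23.discounted_pfs_months, o34.discounted_pfs_months)
            )
    return pd.DataFrame(
        rows,
        columns=["reward_timing", "discount_timing",
                 "months_two_three", "months_three_four"],
    )


def base_case(config: AnalysisConfig, probs: dict[str, float] | None = None) -> dict[str, Any]:
    """Base-case cohort runs, Table-3-shaped summary, ICER and NMB."""
    if probs is None:
        probs = derive_monthly_probs(config)
    scenario = build_scenario(config, probs["prob_two_three"], probs["prob_three_four"])
    trace23, o23 = run_cohort(scenario.model, scenario.two_three)
    trace34, o34 = run_cohort(scenario.model, scenario.three_four)
    cea = icer(o23, o34)
    nmb23, nmb34 = nmb(o23, scenario.rule), nmb(o34, scenario.rule)
    summary = pd.DataFrame(
        {
            "strategy": ["three_four_month", "two_three_month"],
            "effect_qaly": [round(o34.discounted_qaly, 3), round(o23.discounted_qaly, 3)],
            "incremental_effect": [0.0, round(cea.delta_effect, 3)],
            "cost_usd": [round(o34.discounted_cost, 2), round(o23.discounted_cost, 2)],
            "incremental_cost": [0.0, round(cea.delta_cost, 2)],
            "icer_usd_per_qaly": [0.0, round(cea.icer, 2) if np.isfinite(cea.icer) else np.nan],
        }
    )
    for o in (o23, o34):
        logger.info(
            "%s: %.4f QALYs, $%.2f, %.3f discounted PFS-months",
            o.name, o.discounted_qaly, o.discounted_cost, o.discounted_pfs_months,
        )
    return {
        "scenario": scenario,
        "trace_two_three": trace23,
        "trace_three_four": trace34,
        "outcome_two_three": o23,
        "outcome_three_four": o34,
        "cea": cea,
        "nmb_two_three": nmb23,
        "nmb_three_four": nmb34,
        "preferred": scenario.preferred(),
        "summary": summary,
    }


def run_full_analysis(
    config: AnalysisConfig, outdir: str | Path | None = None
) -> dict[str, Any]:
    """Execute pool -> derive probabilities -> base case -> DSA -> PSA.

    Returns the report bundle; with ``outdir`` also writes summary,
    tornado, two-way grids, CEAC and trace CSVs plus a JSON report.
    Deterministic for a fixed configuration (the PSA seed lives in the
    configuration), so re-runs produce byte-identical files.
    """
    violations = validate_config(config)
    if violations:
        raise PipelineError("config", "; ".join(violations))

    report: dict[str, Any] = {"config": config.to_dict()}

    # evidence synthesis
    pooled = None
    if config.study_table is not None:
        pooled = _pool_from_table(config)
        report["pooling"] = {
            k: {
                "estimate": p.estimate, "ci_low": p.ci_low, "ci_high": p.ci_high,
                "i2": p.i2, "tau2": p.tau2, "q_stat": p.q_stat, "df": p.df,
                "p_het": p.p_het, "k": p.k, "n_total": p.n_total,
            }
            for k, p in pooled.items()
        }

    # survival -> rate -> monthly probability
    try:
        if pooled is not None:
            probs = derive_monthly_probs(
                config, pooled["two_three"].estimate, pooled["three_four"].estimate
            )
        else:
            probs = derive_monthly_probs(config)
    except ValueError as exc:
        raise PipelineError("transitions", str(exc)) from exc
    probs["rate_two_three"] = rate_from_survival(
        probs["survival_two_three"], config.horizon_months
    )
    probs["rate_three_four"] = rate_from_survival(
        probs["survival_three_four"], config.horizon_months
    )
    logger.info(
        "monthly probabilities: %.4f (from S=%.4f), %.4f (from S=%.4f); convention %s/%s",
        probs["prob_two_three"], probs["survival_two_three"],
        probs["prob_three_four"], probs["survival_three_four"],
        config.reward_timing, config.discount_timing,
    )
    report["transitions"] = probs

    # base case + convention diagnostic
    base = base_case(config, probs)
    report["base_case"] = base
    diag = implied_months_by_convention(config, probs)
    report["implied_months_by_convention"] = diag
    logger.info("implied discounted PFS-months by convention:\n%s", diag.to_string(index=False))

    # deterministic sensitivity analyses
    scenario = base["scenario"]
    params = default_param_specs(config, scenario)
    tornado = one_way(params, scenario, NMBTarget.STRATEGY_2_3)
    tornado_df = pd.DataFrame(
        [(e.param, e.nmb_at_low, e.nmb_at_high, e.swing) for e in tornado],
        columns=["param", "nmb_low", "nmb_high", "swing"],
    )
    by_name = {p.name: p for p in params}
    top3 = [by_name[e.param] for e in tornado[:3]]
    grids = {}
    for i in range(len(top3)):
        for j in range(i + 1, len(top3)):
            a, b = top3[i], top3[j]
            grids[f"{a.name}__{b.name}"] = two_way(
                a, b, config.two_way_grid_points, scenario
            )
    p23_threshold = threshold(by_name["p_two_three"], scenario)
    report["dsa"] = {
        "tornado": tornado_df,
        "two_way": grids,
        "threshold_p_two_three": p23_threshold,
    }

    # probabilistic sensitivity analysis
    assignments = psa_mod.assign_distributions(params, config.range_semantics)
    samples = psa_mod.run_psa(scenario, assignments, config.psa_n, config.psa_seed)
    wtp_grid = np.arange(0.0, config.wtp_grid_max + 1e-9, config.wtp_grid_step)
    curve = psa_mod.ceac(samples, wtp_grid)
    ceac_df = pd.DataFrame(
        [(c.wtp, c.prob_2_3_preferred, c.prob_3_4_preferred) for c in curve],
        columns=["wtp", "prob_2_3", "prob_3_4"],
    )
    at_wtp = psa_mod.ceac(samples, [config.wtp])[0]
    report["psa"] = {
        "n_draws": config.psa_n,
        "seed": config.psa_seed,
        "ceac": ceac_df,
        "prob_2_3_at_wtp": at_wtp.prob_2_3_preferred,
    }
    logger.info(
        "PSA: P(two_three preferred | WTP=%.0f) = %.3f over %d draws",
        config.wtp, at_wtp.prob_2_3_preferred, config.psa_n,
    )

    if outdir is not None:
        _write_bundle(report, Path(outdir))
    return report


def _write_bundle(report: dict[str, Any], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    base = report["base_case"]
    base["summary"].to_csv(outdir / "summary.csv", index=False)
    base["trace_two_three"].to_frame().to_csv(outdir / "trace_two_three.csv", index=False)
    base["trace_three_four"].to_frame().to_csv(outdir / "trace_three_four.csv", index=False)
    report["implied_months_by_convention"].to_csv(
        outdir / "implied_months_by_convention.csv", index=False
    )
    report["dsa"]["tornado"].to_csv(outdir / "tornado.csv", index=False)
    for name, grid in report["dsa"]["two_way"].items():
        grid.to_csv(outdir / f"two_way_{name}.csv", index=False)
    report["psa"]["ceac"].to_csv(outdir / "ceac.csv", index=False)

    cea = base["cea"]
    machine = {
        "config": report["config"],
        "pooling": report.get("pooling"),
        "transitions": report["transitions"],
        "base_case": {
            "two_three": {
                "qaly": base["outcome_two_three"].discounted_qaly,
                "cost": base["outcome_two_three"].discounted_cost,
                "pfs_months": base["outcome_two_three"].discounted_pfs_months,
            },
            "three_four": {
                "qaly": base["outcome_three_four"].discounted_qaly,
                "cost": base["outcome_three_four"].discounted_cost,
                "pfs_months": base["outcome_three_four"].discounted_pfs_months,
            },
            "delta_cost": cea.delta_cost,
            "delta_effect": cea.delta_effect,
            "icer": cea.icer,
            "classification": cea.classification.value,
            "nmb_two_three": base["nmb_two_three"],
            "nmb_three_four": base["nmb_three_four"],
            "preferred": base["preferred"],
        },
        "dsa": {
            "tornado_ranking": report["dsa"]["tornado"]["param"].tolist(),
            "threshold_p_two_three": report["dsa"]["threshold_p_two_three"],
        },
        "psa": {
            "n_draws": report["psa"]["n_draws"],
            "seed": report["psa"]["seed"],
            "prob_2_3_at_wtp": report["psa"]["prob_2_3_at_wtp"],
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(machine, fh, indent=2, sort_keys=True)
        fh.write("\n")
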