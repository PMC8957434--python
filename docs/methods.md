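# Methods

## Decision problem and model structure

Two post-ablation surveillance schedules for early-stage HCC are compared
over a 2-year horizon: visits every 2–3 months versus every 3–4 months.
More frequent visits detect recurrence earlier (a higher 2-year
recurrence-free survival in the pooled evidence) at a higher monthly
follow-up cost. The model is a two-state discrete-time Markov cohort:
progression-free survival (PFS) and a single absorbing
progression-or-death (PD) state, with a constant monthly transition
probability per schedule. The cycle length is one month and the horizon
24 cycles; no tunnel states, time-varying hazards, or post-progression
pathway are modelled — the comparison deliberately stops at progression,
where the two schedules cease to differ.

Costs are direct follow-up costs only (imaging plus laboratory work,
USD), charged per month spent in PFS; the PFS utility weight converts
PFS-months into QALYs (`QALY = months × u / 12`). Because cost and QALY
are both exact multiples of the same discounted PFS-month total, their
ratio structure is transparent and the discounted-months figure is the
single diagnostic that characterises a run.

## Parameters

| parameter | default | range in SA | units / notes |
|---|---|---|---|
| monthly P(PFS→PD), intensive | 0.0118 | 50%–200% (beta) | from 2-y RFS 0.752 |
| monthly P(PFS→PD), relaxed | 0.0251 | 50%–200% (beta) | from 2-y RFS 0.543 |
| monthly cost, intensive | $117.16 | 50%–200% (gamma) | per PFS-month |
| monthly cost, relaxed | $78.10 | 50%–200% (gamma) | per PFS-month |
| utility, PFS | 0.76 | 0.61–0.91 (beta) | per year |
| utility, PD | 0.68 | 0.54–0.82 (beta) | inert by default (absorbing PD) |
| annual discount | 5% | 0–5% (fixed in PSA) | costs and QALYs |
| WTP threshold | $10,888/QALY | — | 1× 2020 Chinese GDP per capita |

The monthly probabilities come from the pooled survivals by the
constant-hazard identity `p = 1 − exp(ln(S)/24)`. Downstream stages use
the 4-decimal (printed) probabilities by default so the pipeline matches
its published inputs; `use_printed_probs=False` switches to full
precision. The PD utility is representable (and samplable) so it can
participate in sensitivity analyses, but with an absorbing PD state it
accrues nothing unless the `pd_accrues_utility` model variant is enabled;
its tornado bar is correctly zero by default.

## Reward and discounting conventions

Commercial cohort-model tools rarely document when within a cycle rewards
accrue or how an annual discount is stepped, and the choice moves 2-year
results by several percent. Both are explicit here:

* reward timing: `end_of_cycle` (default), `start_of_cycle`, or
  `half_cycle` (trapezoidal average of the adjacent discounted
  occupancies, so `start ≥ half ≥ end` always);
* discounting: `continuous_monthly` (`(1+r)^(−t/12)`, default) or
  `annual_step` (`(1+r)^(−⌊t/12⌋)`).

Under the default convention the discounted PFS-months are 19.785
(intensive) and 16.949 (relaxed), giving 1.2531 / 1.0734 QALYs and
$2318.03 / $1323.73. The published summary implies 18.89 and 16.25
months (published cost ÷ monthly cost), i.e. 1.196 / 1.029 QALYs — about
4.8% / 4.3% below the end-of-cycle figures, and *every* convention
exposed here yields more months than the published figures imply, so the
originating tool's exact accumulation cannot be reconstructed. The
package therefore treats conventions as configuration, reports the
implied-months diagnostic for all six combinations
(`implied_months_by_convention`), and compares summary-level results at
5% relative tolerance. The qualitative conclusions (ICER far below WTP;
preference order; tornado ranking) are identical across conventions.

The base-case ICER under the default convention is $5,536/QALY versus
$5,651/QALY implied by the published rounded summary; both are computed,
the former by the cohort engine and the latter by the ICER identity on
the printed per-strategy values.

## Evidence synthesis

Pooling is inverse-variance with DerSimonian–Laird random effects,
implemented directly from the moment equations (the formulas are part of
the pipeline's contract) and cross-checked in the test suite against
`statsmodels.stats.meta_analysis.combine_effects(method_re="dl")`. The
default scale is the raw proportion with binomial variance `p(1−p)/n`;
a logit-scale option (variance `1/(np(1−p))`, back-transformed CI) is
provided, and the two agree to well under 0.01 for mid-range proportions
like those pooled here. Boundary proportions (0 or 1) receive a `0.5/n`
continuity correction with a logged warning. The 95% CI multiplier is
fixed at 1.96. No small-sample (Knapp–Hartung) correction, arcsine-type
transform, or publication-bias diagnostic is applied.

## Synthetic evidence generator

Per-study 2-year RFS values for the underlying evidence base were
digitized from survival curves and never printed, so fixtures cannot
reproduce them study-by-study. The generator instead emulates the
*assumed* data-generating process of the random-effects model:
`logit(π_k) ~ Normal(logit(p_true), τ²)`, `survivors ~ Binomial(n_k, π_k)`,
`rfs = survivors/n_k`. Random effects live on the logit scale so latent
proportions stay in (0,1). Defaults match the published evidence
structure: per-study sizes {117, 52, 71, 62, 43, 159} (four RCTs, two
retrospective; 504 patients, true RFS 0.752) and
{170, 183, 438, 62, 167, 122, 115, 109, 70} (three RCTs, six
retrospective; 1436 patients, true RFS 0.543). τ² on the logit scale
defaults to 0.05 for both groups, chosen once to produce the
moderate-to-substantial heterogeneity (I² broadly in the 50–75% band in
expectation at these study sizes) that the pooled evidence reports; no
value was published. Each group draws from its own stream at a fixed
seed offset (+1,000,003), so groups are independently reproducible. The
generator produces 24-month binary status only — no event times,
censoring, or survival curves — so recovery tests validate the pooling
chain, not curve digitization.

Coverage behaviour: across 500 seeded replicates of the 6-study group,
the DL 95% CI covers the generating truth in ≈91% of replicates —
slightly below nominal, the known small-k behaviour of the DL interval —
which the acceptance test bounds at ≥90%.

## Sensitivity analyses

One-way analysis re-runs the model at each parameter's range limits with
the others at base and reports the NMB swing, sorted tornado-style. The
default target is the *absolute* NMB of the intensive strategy (this is
what reproduces the published ranking, with PFS utility the widest bar);
an incremental-NMB target is an option, under which the reference
strategy's parameters also matter. Cost parameters act linearly through
the discounted-months multiplier, so endpoints fully characterise their
bars. Threshold analysis scans the incremental NMB on a 401-point grid
and refines each sign change by Brent bisection to 1e−6 of the range;
non-monotone ranges return all crossings with a warning. The
intensive-schedule progression probability crosses at ≈0.0194 under the
default convention (the published bound is "below 0.024"; the exact
crossing depends on the unrecoverable convention, so it is treated as
qualitative). Two-way analysis labels each grid cell with the
NMB-preferred strategy via the same decision rule as the base case.

## Probabilistic sensitivity analysis

Distributions are moment-matched: gamma for costs
(`shape = (mean/sd)², scale = sd²/mean`), beta for probabilities and
utilities (`α+β = mean(1−mean)/sd² − 1`), with the mean at the base
value. The published ranges carry no stated semantics; the default reads
them as 95% plausible intervals (`sd = range/3.92`), with a `minmax`
option (`sd = range/√12`). Parameters are sampled independently (no
correlation structure was published); the discount rate stays fixed.
Sampling uses one root seed with per-parameter substreams spawned in
declaration order, so appending a parameter leaves earlier draws
untouched. Each draw re-runs both cohorts and the per-draw winner uses
the same NMB tie-breaking as the base-case rule, so CEAC and decision
rule cannot disagree.

At the WTP threshold the intensive schedule is preferred in ≈73% of
10,000 draws (seed 42). The published figure is 100%, which is not
attainable under any moment-matched reading of the published ranges: the
50%–200% cost range alone gives the intensive strategy's cost a standard
deviation of ≈$45/month (≈$887 of NMB), against a mean incremental NMB
of ≈$964. The published PSA evidently used tighter (unstated)
distribution parameters; the package reports what its stated inputs
produce. The degenerate all-fixed PSA collapses every draw to the base
case and its CEAC steps exactly at the base-case ICER (ties go to the
cheaper reference), which is verified in the tests.

## Numerical choices and limitations

* The cohort trace is validated against the geometric closed form
  `r(1−r^N)/(1−r)`, `r = (1−p)·d`, to 1e−9 over random inputs; the
  closed form falls back to a direct sum within 1e−12 of `r = 1`.
* Beta/gamma fits reproduce their target moments to 1e−9; infeasible
  beta moments (`sd² ≥ mean(1−mean)`) fail before any sampling.
* NMB ties resolve to the lower-cost strategy, then to the reference —
  a conservative-spending convention.
* Monetary outputs are rounded to 2 decimals and effects to 3 in the
  human-readable summary; machine-readable outputs keep full precision.
* Problem sizes in the test suite: 10,000-draw PSA for the acceptability
  check, 500 replicates for coverage, 1000 random pairs for the engine
  oracle — sizes at which the Monte Carlo error is far below the margins
  being tested, while a full suite run stays in single-digit seconds.
* Scope limits: exactly two strategies (no efficiency frontiers or
  extended dominance), no EVPI, no correlated sampling, no
  post-progression modelling, and no currency conversion beyond the
  recorded RMB 6.56/USD metadata constant.
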