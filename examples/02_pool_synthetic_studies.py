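"""Generate a synthetic evidence base and pool it with DL random effects.

The generator mirrors the published evidence structure: 6 studies / 504
patients (true pooled 2-y RFS 0.752) vs 9 studies / 1436 patients (true
0.543), with logit-normal between-study heterogeneity.
"""

from rfacea import emulate_reference_cohort, pool_proportions

g23, g34 = emulate_reference_cohort(seed=1)

for label, studies, truth in (
    ("2-to-3-month", g23, 0.752),
    ("3-to-4-month", g34, 0.543),
):
    pooled = pool_proportions(studies)  # DerSimonian-Laird, raw scale
    print(f"{label} group ({pooled.k} studies, {pooled.n_total} patients):")
    print(f"  pooled 2-y RFS {pooled.estimate:.3f} "
          f"(95% CI {pooled.ci_low:.3f}-{pooled.ci_high:.3f}), "
          f"I^2 = {100 * pooled.i2:.1f}%, tau^2 = {pooled.tau2:.5f}"
          f"   [generating truth {truth}]")

print("\nThe CI should usually cover the generating truth; I^2 reflects the")
print("between-study variance injected on the logit scale (tau^2 = 0.05).")
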