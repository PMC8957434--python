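"""Base-case cost-effectiveness comparison of the two surveillance intervals.

Runs both 24-cycle cohorts (monthly probabilities 1.18% / 2.51%, monthly
costs $117.16 / $78.10, PFS utility 0.76, 5%/yr discount) and compares
them by ICER and net monetary benefit at WTP $10,888/QALY.
"""

from rfacea import AnalysisConfig, base_case, implied_months_by_convention

config = AnalysisConfig()
result = base_case(config)

print(result["summary"].to_string(index=False))
o23, o34 = result["outcome_two_three"], result["outcome_three_four"]
print(f"\nDiscounted PFS-months: {o23.discounted_pfs_months:.2f} vs "
      f"{o34.discounted_pfs_months:.2f}")
print(f"NMB at WTP $10,888/QALY: {result['nmb_two_three']:.2f} vs "
      f"{result['nmb_three_four']:.2f}  ->  preferred: {result['preferred']}")

print("\nImplied discounted PFS-months by reward/discount convention")
print("(divide a published cost by the monthly cost to identify a tool's convention):")
print(implied_months_by_convention(config).to_string(index=False))
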