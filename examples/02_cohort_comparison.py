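"""Compare vitiligo-like and IGH-like phantom cohorts.

Simulates 8 + 8 labelled scans, analyses each, and prints the per-group
metric summaries with two-sided Wilcoxon rank-sum p-values.  The expected
pattern mirrors the clinical one: IGH-like lesions show a steeper
boundary slope and higher local SD, vitiligo-like lesions a deeper
relative PA peak.
"""

from paskin import (analyze_cohort, generate_cohort, igh_like_config,
                    vitiligo_like_config)

scans = generate_cohort(vitiligo_like_config(), igh_like_config(),
                        n_vit=8, n_igh=8, seed=42)
result = analyze_cohort([volume for volume, _ in scans])

print(result.group_summary.round(4).to_string())
print()
for metric, p in result.p_values.items():
    flag = "*" if p < 0.05 else " "
    print(f"p[{metric:>17s}] = {p:.4g} {flag}")
print("\n(* two-sided rank-sum p < 0.05; no multiple-testing correction)")
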