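"""Generate a two-group clinical cohort and run the statistics layer.

The copula cohort reproduces the study's group margins (252 allergic vs
200 control eyes) and its reported rank correlations.  The script prints
the normality-gated group comparisons and the recovered correlations.
"""

from meibomorph import compare_groups, correlation_matrix, encode_sex, scenarios
from meibomorph.synthetic import generate_cohort

table = generate_cohort(scenarios.cohort_spec(seed=1))
print(f"cohort: {len(table)} eyes ({dict(table.group.value_counts())})\n")

print(f"{'variable':<16} {'test':<12} {'allergy':>14} {'control':>14} {'p':>10}")
for var in ("tmh_mm", "nibut_first_s", "nibut_avg_s", "congestion", "osdi"):
    res = compare_groups(table, var)
    (m1, s1, _), (m2, s2, _) = (res.group_summaries[g] for g in sorted(res.group_summaries))
    print(f"{var:<16} {res.test_name:<12} {m1:7.2f}+/-{s1:<5.2f} {m2:7.2f}+/-{s2:<5.2f} {res.p_value:10.2g}")

allergic = table[table.group == "allergy"].copy()
allergic["sex"] = encode_sex(allergic["sex"])
corr, _ = correlation_matrix(
    allergic, ["gland_count", "nibut_first_s", "dropout_ratio", "osdi", "age_years", "sex"]
)
print("\nrecovered Spearman correlations (allergic group):")
print(f"  gland count ~ first TBUT : {corr.loc['gland_count', 'nibut_first_s']:+.3f}  (target -0.21)")
print(f"  dropout     ~ OSDI       : {corr.loc['dropout_ratio', 'osdi']:+.3f}  (target -0.24)")
print(f"  dropout     ~ age        : {corr.loc['dropout_ratio', 'age_years']:+.3f}  (target -0.19)")
print("Targets are imposed through the Gaussian copula; recovery is within sampling error (~2/sqrt(n)).")
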