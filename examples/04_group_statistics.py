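"""Between-group statistics: outcome chi-square and per-feature contrasts.

The 2x2 outcome test uses the uncorrected Pearson chi-square; feature
contrasts pair a Kruskal-Wallis rank test (= Mann-Whitney for two groups)
with Student's t-test.
"""

from surgesture import (CohortConfig, ContingencyTable2x2, default_taxonomy,
                        feature_matrix, generate_cohort, group_feature_tests,
                        pearson_chi2, proportion_pct)

# Vascular-injury outcome table for a 49-competent / 26-incompetent cohort:
# 3 of 49 competent (6.1%) vs 8 of 26 incompetent (30.8%) cases injured.
stat, dof, p = pearson_chi2(ContingencyTable2x2(46, 3, 18, 8))
print(f"vascular injury: chi2 = {stat:.3f} (dof {dof}), p = {p:.3f}; "
      f"rates {proportion_pct(3, 49)}% vs {proportion_pct(8, 26)}%")

tax = default_taxonomy()
cases, _, outcomes = generate_cohort(CohortConfig(seed=5, n_videos=150,
                                                  n_surgeons=66), tax)
fm = feature_matrix(cases, tax)
labels = (outcomes.loc[fm.index, "true_group"] == "incompetent").astype(int).to_numpy()
tests = group_feature_tests(fm, labels)
top = tests.nsmallest(5, "kw_p")
print("\nstrongest group contrasts (rank test):")
for feat, row in top.iterrows():
    arrow = "higher" if row["direction"] > 0 else "lower"
    print(f"  {feat:22s} p = {row['kw_p']:.2e}  ({arrow} in incompetent group)")
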