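"""Synthetic two-area cohort and the full statistical comparison.

Generates a cohort with the published V1/V2m summary statistics, then runs
the analysis battery: Fisher's exact test on the published BAC-firing
counts, KS and t tests on the synthetic cohort, the exact 1-D two-group
split of the pooled ADP values, and the length-ADP linear fit.
"""

from ttl5sim import stats as st
from ttl5sim.synth import CohortParams, gen_cohort

fisher = st.fisher_exact_2x2(st.ContingencyTable(((10, 11), (1, 17))))
print(f"Fisher (BAC firing 10/21 vs 1/18): p = {fisher.p_value:.2g}")

tab = gen_cohort(CohortParams(seed=7))
adp = tab.by_area("max_adp_integral")
lengths = tab.by_area("trunk_length_um")

ks = st.ks_two_sample(adp["V1"], adp["V2m"])
print(f"KS on max ADP integral: D = {ks.statistic:.2f}, "
      f"p = {ks.p_value:.2g}")

tt = st.two_sample_t(lengths["V1"], lengths["V2m"])
print(f"t test on trunk length: t = {tt.statistic:.2f}, "
      f"p = {tt.p_value:.2g}")

pooled = tab.frame["max_adp_integral"].to_numpy()
labels, boundary = st.split_two_groups_1d(pooled)
frac_v1 = labels[tab.frame["area"] == "V1"].mean()
frac_v2m = labels[tab.frame["area"] == "V2m"].mean()
print(f"two-group ADP split at {boundary:.0f} mV·ms: "
      f"high-ADP fraction V1 = {frac_v1:.2f}, V2m = {frac_v2m:.2f}")

fit = st.linear_fit_ftest(tab.frame["trunk_length_um"],
                          tab.frame["max_adp_integral"])
print(f"length-ADP fit: r² = {fit.extras['r2']:.3f}, p = {fit.p_value:.2g}")

print()
print("The synthetic cohort reproduces the analysis structure: smaller ADP")
print("and shorter trunks in V2m, a positive pooled length-ADP relation,")
print("and a cfADP-like high/low split dominated by V1 cells.")
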