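"""Subgroup-stratified clinical statistics: BRAF association, Kaplan-Meier
curves, log-rank test, and the Cox hazard ratio; plus the packaged
18-patient clinical summary table.
"""

import numpy as np

import leatsubtype as L

_, clinical, truth = L.generate_cohort(L.CohortConfig(seed=1))
table = clinical.set_index("sample_id")

# association of the BRAF marker with the planted subgroups
_, assoc = L.cluster_marker_association(truth.subgroup, table["braf"] == "V600E")
print("BRAF vs subgroup (one-vs-rest Fisher):")
print(assoc[["n_marker", "n_total", "odds_ratio", "pval", "qval"]].round(4).to_string())

# survival stratified by BRAF status
mutant = (table["braf"] == "V600E").to_numpy()
t = table["pfs_time"].to_numpy()
e = table["pfs_event"].to_numpy()
km_wt = L.km_estimate(t[~mutant], e[~mutant])
km_mut = L.km_estimate(t[mutant], e[mutant])
chi2, p = L.logrank_test([(t[~mutant], e[~mutant]), (t[mutant], e[mutant])])
cox = L.cox_hr(t, e, mutant.astype(int))
print(f"median PFS: wild-type {km_wt.median:.1f} vs BRAF-mutant {km_mut.median:.1f} months")
print(f"log-rank chi2 = {chi2:.2f} (p = {p:.4f}); "
      f"Cox HR = {cox.hr:.2f} [{cox.ci_low:.2f}, {cox.ci_high:.2f}]")

# packaged clinical fixture
fixture = L.load_table1_fixture()
print(f"clinical table: {len(fixture)} patients, "
      f"{(fixture['engel'] == 'Ia').sum()} Engel Ia, "
      f"{(fixture['recurrence'] == 'yes').sum()} recurrences, "
      f"diagnoses {fixture['diagnosis'].value_counts().to_dict()}")
print("-> BRAF-mutant samples concentrate in one subgroup and progress "
      "several times faster; at 53 samples the estimated HR scatters "
      "widely around the generator's true hazard ratio of 4.")
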