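"""Summarize the demographics of the packaged familial SCAD cohort.

Loads the 15-family roster and prints the cohort summary: sample sizes,
sex proportion, age-at-first-event statistics for the SCAD patients, and
clinical feature counts (FMD = fibromuscular dysplasia, ES = emotional
stress trigger, CT = coronary tortuosity, ...).
"""

from famscad import datasets, summarize_cohort

summary = summarize_cohort(datasets.load_cohort_individuals())

print(f"affected-spectrum individuals : {summary.n_total}")
print(f"  with SCAD                   : {summary.n_with_scad}")
print(f"  female                      : {summary.n_female} ({summary.pct_female}%)")
print(
    f"age at first SCAD event       : {summary.mean_age_first_scad} "
    f"+/- {summary.sd_age_first_scad} yrs, range {summary.age_range_scad}"
)
print(
    f"age at diagnosis, all affected: {summary.mean_age_diagnosis_all} "
    f"+/- {summary.sd_age_diagnosis_all} yrs, range {summary.age_range_all}"
)
print("clinical features among SCAD patients:")
for feature, count in sorted(summary.feature_counts.items()):
    print(f"  {feature:5s} {count}")
print(f"families with recurrent SCAD  : {summary.n_recurrent_families}")
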