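"""Expected clinical utility of alert rules at a fixed alert prevalence.

For each prediction model, the risk threshold is set to the 90th percentile
of predicted risk (10% of admissions alert), and the rule is scored with
the expected risk difference (eRD), number needed to benefit (NNB), and
net benefit (NB) under the model-augmented decision tree (no alert ->
usual care) and the observed exchange rate, under which usual care's net
benefit is zero.
"""

import alertvalue as av

cohort = av.generate_cohort(av.study_config(n_patients=20_000, seed=11))

reports = [
    av.utility_report(
        cohort,
        av.threshold_for_prevalence(cohort, model, 0.10),
        tree=av.TREE2,
        exchange_rate="observed",
    )
    for model in cohort.model_names
]
table = av.reports_to_table(reports, usual_care=av.usual_care_report(cohort))
print(table.round(4).to_string())
print()
best = max(reports, key=lambda r: r.net_benefit)
print(f"best rule: {best.rule.model_name}  "
      f"(eRD {100 * best.erd:.1f}%, NNB {best.nnb:.1f} alerts, "
      f"NB {best.net_benefit:.4f})")
# eRD: extra EOL admissions (as a share of all EOL admissions) that would
# get a CSO if every alert led to one. NNB: alerts needed per additional
# beneficiary. NB > 0 means the rule beats usual care at the clinicians'
# own revealed TP:FP trade-off.
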