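# alertvalue

Decision analysis of mortality-alert rules *before* implementation.

Hospitals increasingly consider clinical decision support systems (CDSS)
that alert clinicians to admissions with a high predicted risk of death
within one year, prompting a goals-of-care discussion and a code status
order (CSO). Validation studies report discrimination (the C-statistic),
but discrimination says little about whether an alert rule would add value
over what clinicians already do. `alertvalue` is a library for quality
improvement teams and biostatisticians who want to answer that question
from retrospective data, before any system is built: given a cohort of
hospitalizations with model-predicted risks, end-of-life (EOL) outcomes,
and usual-care CSO documentation, it computes the expected clinical
utility of alert rules and compares them with usual care.

## The model

An alert rule *R* fires when predicted risk ≥ a threshold, chosen as the
empirical (1 − p) quantile of risk so that a fraction *p* of admissions
alert (the **alert prevalence**, the workload dial). Assuming every alert
leads to a CSO, outcomes unfold under one of two decision trees:
**tree 1** (conventional decision-curve analysis): no alert → no CSO;
**tree 2** (model-augmented care): no alert → usual care. A true positive
(TP) is a CSO during an EOL hospitalization; a false positive (FP) is a
CSO for a patient who survives the year. The metrics are

- expected risk difference
  `eRD = P(Alert ∨ CSO | EOL) − P(CSO | EOL)`,
- number needed to benefit
  `NNB = P(Alert) / (P(Alert ∧ EOL) − P(Alert ∧ EOL ∧ CSO))`,
- net benefit `NB_S = P(TP | S) − P(FP | S) × e`, where the exchange
  rate *e* is either the conventional threshold odds `t/(1−t)` or the
  **observed exchange rate**
  `e = P(TP | usual care) / P(FP | usual care)` — clinicians' revealed
  TP:FP trade-off, under which usual care has `NB = 0` by construction.

On top of these: decision curves over threshold or prevalence grids,
two-way sensitivity tile maps (prevalence × exchange rate, per subgroup),
subgroup expected relative risks, 2×2 odds ratios, a two-stage
(patient-level) bootstrap, and a calibrated synthetic-cohort generator so
the whole pipeline runs without access to protected data.

## Worked example

```python
import alertvalue as av

cohort = av.generate_cohort(av.study_config(n_patients=20_000, seed=11))
reports = [av.utility_report(cohort,
                             av.threshold_for_prevalence(cohort, m, 0.10),
                             tree=av.TREE2, exchange_rate="observed")
           for m in cohort.model_names]
print(av.reports_to_table(reports, usual_care=av.usual_care_report(cohort))
        .loc[["erd", "nnb", "net_benefit"]].round(4).to_string())
```

```
metric       rf_admindemodx  rf_admindemo   mhomr  rf_minimal  usual_care
erd                  0.0769        0.1017  0.0977      0.0983         NaN
nnb                  7.8235        5.9111  6.1574      6.1149         NaN
net_benefit          0.0058        0.0009 -0.0006     -0.0012      0.0000
```

At a 10% alert prevalence, every rule would raise CSO coverage among EOL
admissions by ~8–10 percentage points (eRD) at roughly 6–8 alerts per
additional beneficiary (NNB) — yet at the revealed TP:FP trade-off only
the two most discriminative models beat usual care (net benefit > 0),
and two would destroy value. Predictiveness is not utility.

The `examples/` scripts walk through each capability (simulation,
rule evaluation, decision curves, sensitivity tiles, bootstrap CIs), and
the `alertvalue` CLI exposes the same stages
(`simulate / evaluate / curves / sensitivity / bootstrap`) for shell
pipelines. See `docs/methods.md` for the statistical details and design
choices.

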