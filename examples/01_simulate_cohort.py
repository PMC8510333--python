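"""Generate a synthetic hospital cohort and inspect its margins.

The generator emulates an alerting-eligible acute-care population: ~17% of
admissions are at the end of life (EOL, death within 1 year), ~35% carry a
usual-care code status order (CSO) overall and ~69% among EOL admissions,
with per-model risk scores of chosen discrimination.
"""

import alertvalue as av

# study_config() calibrates the CSO propensity parameters so the generated
# margins hit (35% overall, 69% among EOL); here scaled down for speed.
config = av.study_config(n_patients=10_000, seed=7)
cohort = av.generate_cohort(config)

s = av.cohort_summary(cohort)
print(f"admissions          : {s.n}")
print(f"EOL fraction        : {s.n_eol / s.n:.3f}   (target 0.17)")
print(f"CSO fraction        : {s.n_cso / s.n:.3f}   (target 0.35)")
print(f"CSO among EOL       : {s.n_cso_and_eol / s.n_eol:.3f}   (target 0.69)")
for model in cohort.model_names:
    c = av.c_statistic(cohort.risks(model), cohort.eol)
    print(f"C-statistic {model:<15}: {c:.3f}   "
          f"(target {config.target_c[model]:.2f})")
print(f"observed exchange rate: {av.observed_exchange_rate(cohort):.3f}")
# The exchange rate is the usual-care TP:FP ratio — how many EOL CSOs
# clinicians document per non-EOL CSO. ~0.5 means about two non-EOL CSOs
# for every EOL CSO.
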