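# Methods

## Analysis unit and data model

The unit of analysis is the hospitalization (admission), not the patient:
a CDSS would alert per admission, and the main analysis keeps all
admissions. A cohort row carries a binary EOL flag (death within one year
of admission), a binary usual-care CSO flag, one predicted risk in [0, 1]
per model, optional categorical subgroup labels, and an optional
within-patient admission sequence used only by per-patient sampling.
Flags are accepted strictly as 0/1; any other coding must be declared
through an explicit `flag_values` mapping at read time, because silently
coercing `"Y"`/`"TRUE"` is a classic source of miscounts. CSO-to-admission
linkage (date windows around admission) is assumed done upstream; the
library receives an already-linked, already-eligible cohort.

## Alert rules

A rule alerts when risk ≥ threshold. `threshold_for_prevalence` picks the
k-th largest observed risk with k = ceil(p·N), so on tie-free data exactly
ceil(p·N) records alert — the behaviour of percentile thresholding with a
≥ comparison (e.g. 2,204 alerts at p = 0.10 on N = 22,034). Ties at the
threshold all alert and can push the achieved prevalence above the target;
both target and achieved prevalence are carried on the rule, and an
all-ties risk column is flagged degenerate rather than raising. The
uniform-random comparator model is a first-class risk column so every
downstream analysis can include it unchanged; it isolates the effect of
the assumption that *any* alert causes the desired action.

## Utility metrics

All metrics reduce to the 8-cell joint table of (Alert, EOL, CSO):

- tree 1 (model-determined): action = Alert;
- tree 2 (model-augmented): action = Alert ∨ CSO;
- usual care: action = CSO (identical under both trees).

eRD simplifies to P(Alert ∧ ¬CSO ∧ EOL)/P(EOL) and is therefore
non-negative and non-decreasing as the alert set grows. NNB is the
reciprocal risk difference among the alerted; it satisfies
NNB · eRD = P(Alert)/P(EOL) whenever both are defined. An NNB whose
denominator is empty (the rule identifies no EOL admission lacking a CSO)
is reported as NaN, not an exception, because sensitivity grids
legitimately hit such cells. The number-needed-to-screen ×
number-needed-to-treat decomposition of the NNB assumes conditional
independence and is intentionally not implemented; the exact joint-count
formula is.

"Benefit" is P(TP) and "harm" is P(FP) pre-multiplied by the exchange
rate, so net benefit = benefit − harm reads directly off a report. NNB and
all other quantities are stored at full precision; rounding is display
only. The C-statistic uses midranks (ties credited 1/2); the Brier score
is the mean squared risk−outcome difference.

## Exchange rates

Three provenances: `threshold_odds` (t/(1−t), the conventional
decision-curve weight), `observed` (usual-care TP:FP count ratio — the
trade-off clinicians reveal when they decide, under time pressure, whom
to document), and fixed user-supplied values. With the observed rate,
usual care's net benefit is zero by algebraic cancellation, making it the
natural reference line. The observed rate is undefined (error) when usual
care produced no false positives.

## Decision curves

Curves are tidy tables (x, strategy, threshold, exchange rate, net
benefit); plotting is deliberately left to the caller. On a prevalence
axis each model is re-thresholded at every grid point, so models are
compared at equal workload, not equal threshold. Under `threshold_odds`
on a prevalence axis, each model uses the odds of its own
prevalence-derived threshold; the reference strategies (usual care,
alerts-for-all, alerts-for-none), having no threshold of their own, use
the mean of the model odds at that point — a convention documented here
because no principled unique choice exists; a fixed-rate mode sidesteps
the question entirely. Default grids: thresholds 0.01–0.99 (step 0.01),
prevalences 0.05–0.50 (step 0.01) with a 5–20% workload region of
interest recorded in the output metadata. Argmax ties break toward usual
care, then strategy order.

## Sensitivity and subgroups

The two-way grid sweeps alert prevalence × exchange rate and records the
best strategy per cell (net benefit is linear in the rate, so outcomes
are computed once per prevalence and swept). Default rate axis 0.25–2.0,
covering both the observed-rate region (~0.5) and a 1:1 valuation.
Thresholds are fixed on the full cohort by default — one institution-wide
rule evaluated within each subgroup, which is the deployment-relevant
question — with per-subgroup re-thresholding available as an option. Each
grid carries the overall and the subgroup observed exchange rates as
reference lines (NaN when a subgroup has no usual-care FPs).

Subgroup effects report the expected relative risk
ERR = P(Alert ∨ CSO | EOL)/P(CSO | EOL) within each label, with
eRD = (ERR − 1) · P(CSO | EOL) as the linking identity. 2×2 odds ratios
use the Wald log-OR interval (±1.96 SE) without continuity correction;
zero cells yield flagged infinite/undefined ratios.

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes,
not a hospital. Per model, risks come from an equal-variance binormal
latent score — s ~ N(0, 1) for non-EOL, s ~ N(μ, 1) for EOL with
μ = √2 · Φ⁻¹(C) — mapped through the standard logistic function. The
closed form C = Φ(μ/√2) makes discrimination a directly settable dial;
because the C-statistic is rank-based, the logistic map preserves it.
CSO propensity is logistic in the latent score of a designated driver
model, an EOL shift, and additive per-category subgroup offsets; category
draws are independent of EOL and made per admission (a simplification —
real sites/services correlate with case mix). EOL status is drawn once
per patient and shared across that patient's admissions, while risk noise
is per admission; admissions per patient follow a shifted geometric
distribution. No admission dates, lengths of stay or diagnoses are
simulated. Real data differ in ways the generator does not capture —
calibration of risks (latent-logistic risks are *not* calibrated to the
17% prevalence, so Brier scores are larger than a calibrated model's),
site–case-mix correlation, temporal drift — so passing tests demonstrate
correctness of the decision analysis, not realism of any particular
hospital.

Defaults are the reference study conditions: 16,490 patients, mean 1.336
admissions/patient (~22,000 admissions), p_eol = 0.17, four models with
C targets 0.85/0.80/0.79/0.77, two sites (61/39 split, the smaller site
documenting more readily) and three service types with offsets patterned
on published service-level CSO margins, and a CSO risk slope of 0.75
(moderate dependence on predicted risk; any positive value yields the
qualitative "CSO rises with risk" behaviour). `calibrate_cso_params`
solves (intercept, EOL shift) for target (overall, among-EOL) CSO margins
— the defaults are calibrated to (0.35, 0.69) — by two nested Brent root
finds over Gauss–Hermite-quadrature margins (80 nodes; the two equations
are triangular: the non-EOL margin pins the intercept, then the EOL
margin pins the shift). Arithmetically impossible target pairs
(P(CSO|EOL)·p_eol ≥ P(CSO), etc.) raise an infeasibility error. All
randomness flows from one seeded `numpy.random.Generator`; identical
config + seed gives bit-identical cohorts.

## Resampling

The two-stage bootstrap resamples patients with replacement, then one
uniformly random admission per sampled patient copy, respecting
within-patient clustering while matching a one-admission-per-patient
metric convention; this scheme is an interpretation (alternatives, such
as resampling whole admission blocks, can be supplied as custom replicate
generators via the metric callable on `Cohort.take`). Intervals are
percentile 2.5/97.5 — the simplest defensible default; BCa was considered
and deferred. Replicates on which a metric is undefined are dropped and
counted; >10% dropped flags the interval unreliable rather than silently
surviving. Per-patient sampling modes (first/last/random) keep one
admission per patient for sensitivity re-analysis; first/last require the
admission-sequence column.

## Problem sizes in the shipped checks

The test suite exercises the simulator at up to ~100,000 admissions for
margin/discrimination recovery (tolerance ±0.01), runs the brute-force
oracle equivalence on 200 random cohorts of 30–1,000 records at 1e−12,
and estimates bootstrap coverage from 100 repetitions × 200 replicates at
600 patients — sizes chosen to keep Monte-Carlo error well inside the
asserted tolerances while the full suite runs in well under a minute of
simulation time.

## Known limitations

- Alerts are assumed to deterministically cause the action; alert
  fatigue, partial compliance and behavioural co-interventions are out of
  scope (the random comparator makes the assumption's consequences
  visible).
- Synthetic risks are discriminative but not calibrated; analyses that
  depend on absolute risk calibration should not rely on the generator.
- Eligibility filtering (overnight stay, excluded services) is the
  caller's responsibility; the library assumes an eligible cohort.
- No confidence bands are built into curves or tile grids; compose with
  the bootstrap where uncertainty is needed.
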