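# Methods

## The estimand and the linking estimator

For an intervention *j*, availability coverage is the proportion of women
for whom *j* was available at the point where they sought antenatal care:

    AC_j = sum_s c_s * r_sj

with strata *s* = facility type × managing authority × urban/rural location.
`c_s` is the sampling-weighted share of eligible women — most recent live
birth strictly within the last 36 months — who attended four or more ANC
visits (ANC4+) with a care source in stratum *s*; `r_sj` is the
sampling-weighted proportion of facilities in *s* whose readiness checklist
for *j* was fully satisfied on the day of assessment. Linking is at the
stratum level only: the estimator assumes readiness is homogeneous within a
stratum, and it measures *availability*, not receipt — clinical practice
factors that prevent delivery at a ready facility are outside the estimand.

Key conventions, each unit-tested:

- **Recall window** is half-open: `months_since_birth < 36` is eligible, 36
  is not. Negative months are rejected records, not window exclusions.
- **Early ANC enrolment** means first visit in pregnancy months 1–4,
  inclusive of month 4.
- **Readiness is a strict conjunction** over checklist items; a missing item
  flag counts as not available (observed-on-the-day semantics). The default
  checklists (syphilis: test + treatment drug; diabetes: glucose test +
  management drug; hypertensive disorders: BP apparatus + antihypertensive;
  malaria: diagnostic + antimalarial; pre-eclampsia: BP apparatus + urine
  protein test + magnesium sulphate) are editable YAML and are package
  assumptions — real assessment instruments may require more (guidelines,
  trained staff), and stricter checklists can only lower readiness.
- **ANC4+ women without a facility source** form an explicit non-facility
  bucket: they contribute to ANC4+ coverage but zero availability, so
  `sum_s c_s + non_facility_share = ANC4+` holds exactly.
- **Stratum mismatches** between the two survey frames are resolved by a
  collapse cascade: exact match, then drop location, then drop authority —
  never facility type, the strongest determinant of service availability.
  Collapsed readiness is re-aggregated with weighted facility counts, which
  equals recomputing the proportion on the pooled facilities. Strata
  unmatched after the cascade contribute zero and are reported
  (`unmatched_careseeking_share`), never imputed.
- **Component-rate denominators**: the country-level covariate rates (blood
  sample, urine sample, blood pressure, early ANC) are computed over all
  eligible women by default, non-attenders contributing zero, so they sit on
  the same population base as `anc4_rate`; an among-attenders switch
  (`denominator="anc"`) is provided because either convention is defensible.
- All estimates are design-weighted point estimates; weights enter every
  proportion, and every proportion is invariant to rescaling all weights.
  No design-based variance estimation is attempted.

## Fractional logit

Country-level coverage y ∈ [0, 1] is modelled as E[y|x] = logit⁻¹(x'β),
estimated by maximising the Bernoulli quasi-likelihood with IRLS (the
logistic-regression update; the quasi-score is X'(y − μ)). Outcomes exactly
at 0 or 1 are admitted — the quasi-likelihood is finite there at finite β —
and inputs are never clipped. Because the Bernoulli variance function is
misspecified for fractional outcomes, inference uses the HC1 sandwich
covariance, i.e. the robust estimator scaled by n/(n − k), with two-sided
p-values from the normal reference distribution (a t reference would be
equally defensible at n = 20; the normal is used and documented). Note that
statsmodels applies no small-sample factor to GLM sandwich covariances, so
its "HC1" equals HC0 there; the cross-check tests remove the explicit
n/(n − k) factor before comparing.

Numerical choices: IRLS starts at β = 0; convergence is declared when the
maximum relative coefficient change `|Δβ|/(1 + |β|)` falls below `tol`
(default 1e-10) within `max_iter` (default 100); fitted means are floored at
1e-10 from either bound inside the iteration only. A fit that exhausts the
iteration budget or diverges (as under perfect separation, where the
quasi-likelihood has no interior maximum) is returned with
`converged=False` and full diagnostics — never an exception, never a silent
estimate.

**Stepwise selection** is forward with backward pruning: add the candidate
with the smallest robust p-value below 0.1, then remove any included term
with p ≥ 0.1 (worst first), iterating to a fixed point, with at most two
slopes. Ties and iteration order are fixed by the documented candidate
ordering (blood, urine, blood pressure, early ANC, ANC4+), so selection is
deterministic given the data. The direction of stepping (forward-first) is a
package choice among defensible variants; entry and exit thresholds are
equal at 0.1. Non-converged candidate fits are skipped during selection.

**Published coefficient sets** for the five interventions are shipped
verbatim on the logit scale with covariates as proportions — the magnitudes
(e.g. pre-eclampsia intercept −6.44 with blood-sample slope 4.91) are only
coherent on the unit covariate scale. The hypertensive-disorders set carries
its slope on the urine-sample rate as published, although blood-pressure
measurement is the clinically expected predictor for that intervention; the
transcription is kept as-is and flagged rather than silently corrected.

**Default proxy rules** speak percent, as the downstream tool does:
syphilis coverage is a tiered multiple of ANC4+ (20% below 40, 50% on
[40, 75), 70% on [75, 95), 100% at 95 and above — left-closed tiers, "less
than 40" strict), and the four case-management interventions get a flat 5%
of ANC4+. Conversions between percent and proportion happen only at this
module boundary.

## Evaluation metrics

R² is computed as 1 − SS_res/SS_tot about the observed mean — on evaluation
pairs, not as a pseudo-R² of the quasi-likelihood — and can be negative for
a model worse than the mean; the squared Pearson correlation is available as
an alternative reading and equals this R² exactly when the predictions are
least-squares fitted values of the observations. A constant observed vector
makes the correlation (and R²) undefined; they are returned as NaN, never
coerced to 0. Correlation strength is classified as strong (> 0.8), moderate
([0.5, 0.8]) or weak (< 0.5). Reported percentages are rounded half-up to
match integer presentation; full precision is retained internally. Impact
ratios for scale-up scenarios are plain arithmetic, 100 × updated/current,
reported rounded and unrounded.

## What the synthetic data emulate — and what they do not

The household generator produces two-stage cluster samples with mean-one
lognormal weights (σ = 0.35), months-since-birth uniform on 0–59 so the
36-month filter removes ~40%, an ANC visit-count law with P(visits ≥ 4)
matched *exactly* to `p_anc4` (ANC4+ women get 4 + Poisson(1.2) visits; the
rest a zero-inflated Poisson truncated to 0–3) — the ANC4+ margin is the
only visit-count margin the analysis uses — Bernoulli component receipt
among attenders, and a categorical care source over facility strata (plus a
6% non-facility share) drawn only for ANC4+ women, whose residence is set to
the drawn stratum's location. The facility generator allocates at least one
facility to every stratum (the first |S| facilities deterministically), and
arranges item flags so that the *conjunctive* readiness score for each
intervention is an exact Bernoulli draw at the configured stratum rate: each
intervention's signature item (its drug) equals the draw, shared items
(e.g. the BP apparatus) are forced present whenever any intervention
requiring them is ready and otherwise appear at a background rate of 0.85.
Under this design the closed-form truth is
`p_anc4 · sum_s share_s · rate_sj`, which the linked estimator must recover.

The default conditions — ANC4+ 0.55, readiness graded by facility type
(hospitals ≈ 0.85 baseline, health posts ≈ 0.30) with per-intervention
multipliers, eight strata — are fixed, realistic mid-range values for the
settings where both survey types exist. The panel generator draws country
covariate rates uniformly on realistic ranges (e.g. blood-sample rate on
[0.30, 0.95]) and produces coverage as logit⁻¹(x'β + ε), ε ~ N(0, 0.15²).

Not emulated: survey nonresponse and recall error, within-stratum readiness
heterogeneity correlated with care-seeking volume, correlation between a
woman's component receipt and her facility's readiness (a coupling the
analysis never uses — component rates act only as country-level predictors),
geographic structure beyond the stratum labels, and temporal misalignment
between the two surveys. Passing tests therefore demonstrate that the
estimators are correct *under the linking assumptions*, not that those
assumptions hold in any particular country's data.

One property of the panel design deserves emphasis: with noise on the logit
scale, E[logit⁻¹(x'β + ε)] ≠ logit⁻¹(x'β), so the quasi-ML estimand differs
from the generating β by a second-order curvature term of order σ²/2 —
about 0.02 on the intercept at σ = 0.15, shrinking with σ². Because
fractional outcomes carry very small residual variance, replicated panels
can resolve this displacement: the mean estimate over many replicates sits a
few Monte-Carlo standard errors from the generating coefficients even though
every individual fit covers them comfortably (the per-replicate 2-SE
recovery property holds in well over 90% of replicates and is tested). This
is a property of the data-generating process, not an estimator defect.

## Problem sizes and defaults

The packaged study sizes — 2,000 women and 400 facilities per simulated
country by default; 10,000 women and 1,000 facilities for the linking
validation; 20-country panels for model fitting, 500-country panels for
parameter recovery; 16 countries in the end-to-end run — were chosen so that
sampling error is small relative to the effects being checked while a full
run stays in the seconds-to-minutes range. All randomness flows from a
single seed through independent per-stream substreams (household, facility,
panel), so every artifact is reproducible record-for-record.

## Known limitations

- Readiness checklists are assumptions, not the instruments' originals;
  results are conditional on the checklist definition.
- The matching cascade's order (drop location, then authority) is a modelling
  choice; with strongly location-differentiated readiness a different order
  would give different collapsed values.
- Point estimates only: no variance for linked coverage (a cluster bootstrap
  would be the natural extension).
- The fractional logit is linear on the logit scale with at most two
  covariates and no interactions — deliberately minimal for small panels.
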