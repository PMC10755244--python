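# Methods

## Estimand and estimator

The target is the marginal hazard ratio of major adverse cardiovascular
events (MACE) comparing sustained antidepressant treatment against no
treatment in a PTSD cohort followed in discrete 91-day intervals from the
index date (day 0, the first PTSD claim). "Every 3 months" is
operationalized as exactly 91 days on an abstract integer-day calendar;
intervals are half-open `[91k, 91(k+1))` and the final partial interval
keeps its true length.

Treatment probabilities are estimated by pooled logistic regression over
person-periods with a categorical interval term: the denominator model
conditions on the baseline block V (sex, age at index), treatment history
(previous-interval indicator and an ever-treated flag) and the time-varying
block L_k (five comorbidity-class indicators, psychiatric hospitalization;
check-up values in the claims pipeline); the numerator drops L_k. Weights
are cumulative products of observed-treatment probability ratios over each
person's at-risk intervals. Fitted probabilities are clipped to
`[1e-8, 1 - 1e-8]` (clipped rows are counted and logged); exact separation
raises a positivity error naming the covariate pattern rather than
producing silent infinite weights.

The outcome model is a weighted pooled logistic regression of the interval
event indicator on current and previous-interval exposure, V and the
interval term, with person-clustered sandwich covariance (conservative
under estimated weights). Events are rare per interval (<1% at the
defaults, enforced by a parameter check), so exponentiated coefficients are
reported as hazard ratios. The sustained-treatment contrast is computed by
standardization: predicted hazards for every observed row with the
exposure and history terms pinned to each regime, pooled into a
discrete-time odds ratio — the same functional the simulation oracle
reports. The fitting engine is an in-package IRLS with step-halving and a
likelihood-plateau stopping rule (a covariate level carrying no events
drifts to −∞ harmlessly); it is cross-checked against statsmodels in the
test suite.

Previous-interval exposure appears in the outcome model because in the
data-generating process (below) part of the treatment effect on events is
mediated by the documented comorbidity record with one interval of memory;
a current-exposure-only hazard model would be structurally misspecified for
the sustained contrast.

## Synthetic cohort generator

The generator emulates a national-claims follow-up:

- **Latent vulnerability** `S_k`: stationary AR(1), autocorrelation 0.7,
  unit marginal variance. Unobserved by all analysis modules.
- **Expressed severity** `E_k = S_k + τ·A_{k−1}` with τ = 1.0 by default:
  treated patients have systematically more documented psychiatric
  morbidity, a surveillance/coding-intensity effect of being in care.
- **Comorbidity record**: five ICD-10 class indicators (psychotic F2x,
  bipolar F30–31, depressive F32–34, anxiety-related F40–43, somatoform
  F45) emitted per interval with logistic probability increasing in `E_k`
  (slope 0.8; baseline prevalences 2–28%), plus a psychiatric
  hospitalization flag (1% base rate).
- **Prescribing**: treatment log-odds = −3.4 + 0.7·(documented burden) +
  2.2·A_{k−1} + 0.25·female. Assignment depends on latent severity *only
  through the documented record*, so the weight models are correctly
  specifiable from observed data — the property the recovery and
  calibration studies require. About 54% of persons are ever treated over
  12 intervals.
- **Events**: per-interval logistic hazard = −5.2 + ψ·A_k +
  0.5·(S_k + 0.5·burden_k) + 0.04·(age−40) − 0.1·female, with
  ψ = log(1.34) by default. The burden term is scaled by the
  severity-to-event coefficient, so switching that coefficient off removes
  all confounding and mediation at once (the no-confounding limits used in
  tests). Event probability ≈ 0.9% per interval.
- **Censoring**: administrative end after `n_intervals`, plus 1%
  per-interval noninformative dropout. No censoring weights are used.
- **Claims emission**: the same latent panel is written out as persons /
  claims / prescriptions / check-ups tables (PTSD index claim at day 0,
  comorbidity claims with concrete ICD-10 codes, inpatient MACE claims
  with revascularization or brain-imaging flags, cardiovascular deaths,
  WHO-ATC-coded prescriptions, periodic check-ups, an end-of-follow-up
  marker claim). One RNG stream per logical table, derived from the master
  seed, so adding a table never perturbs another. The direct person-period
  path (`simulate_person_periods`) and the claims path reconstructed by the
  cohort builder agree row-for-row on exposure, covariate flags and events;
  the claims path differs only in the dose draws.

This structure yields genuine treatment-confounder feedback: the
comorbidity record is affected by prior treatment, confounds future
treatment (shared latent cause), and mediates part of the prior-treatment
effect — so conventional covariate adjustment is biased toward the null
(for τ > 0) while IPT weighting recovers the truth. That matches the
qualitative pattern the method was designed for: conventional estimates
below the MSM estimate.

The always/never hazard ratio is non-analytic (the logistic hazard is
non-collapsible over S), so the estimand is computed by Monte-Carlo regime
simulation with shared random draws between regimes and a binomial standard
error (conservative given sharing). At the default parameters the oracle
HR is ≈ 1.53: the direct current-exposure effect 1.34 plus the
comorbidity-mediated component.

## What the generator does and does not emulate

It reproduces the measurement structure that matters for the method:
code-based covariates rather than latent severity, claims-based exposure
with WHO-DDD dosing, inpatient/emergency-only outcome adjudication with
in-session procedure requirements, LOCF check-up covariates, last-claim
censoring. It does not emulate Korean billing dialects, medication
non-adherence (dispensing is taken as exposure), calendar seasonality,
mortality-linkage mechanics, or realistic correlation between check-up
values and events (check-ups are noise and serve as LOCF plumbing).
Passing tests therefore demonstrate the statistical machinery under a
faithful measurement model, not clinical realism of any particular
coefficient.

## Eligibility and outcomes

Exclusion rules are applied sequentially for the tally (age ≤ 18 at index;
missing sex, birth year or premium band; never health-checked; MACE before
index; antidepressant before index), though the retained set is
order-invariant. MACE components: I21, or I20/I24 with an in-session
revascularization, count as coronary artery disease with
revascularization; I63 (I60–62) with in-session brain imaging as ischaemic
(haemorrhagic) stroke; deaths with chapter-I causes as cardiovascular
death. Prefix matching includes sub-codes. Outpatient diagnoses never
qualify; non-MACE cardiovascular diagnoses do not end follow-up. Same-day
ties resolve by the fixed order CAD > ischaemic > haemorrhagic > death,
with a logged warning. The "treatment session" is operationalized as the
claim row carrying its own procedure flags.

## Dose–response

Prescription dose in DDDs is `daily_dose_mg × days_supplied / who_ddd_mg`
(packaged WHO ATC reference table; unknown codes are hard errors), with
prescriptions spanning interval boundaries allocated pro-rata by days so
dose mass is conserved. The dose transform is `log(1 + cumulative DDD)`, so
unexposed person-periods enter the model at exactly zero. Dose weights
discretize interval dose into zero plus tertiles of positive dose and use
multinomial numerator/denominator models; a two-level collapse delegates to
the binary machinery and reproduces it exactly. The spline check uses a
clamped B-spline basis of degree 5 on log dose with interior knots at the
{5, 25, 50, 75, 95} percentiles of cumulative DDD among exposed
person-periods; the first basis member is absorbed into the intercept,
which fixes the reference hazard ratio at dose 0 to exactly 1, and basis
columns are rescaled to unit maximum for conditioning.

## Validation studies and their sizes

- **Weight calibration**: one cohort of 20 000 persons × 8 intervals;
  per-interval mean stabilized weight within 3 SE of 1.
- **Recovery**: cohorts of 5 000 persons × 12 intervals with feedback on.
  A single cohort's MSM estimate has MC noise ≈ 0.18 log-HR, so the bias
  is averaged over 1000 replicates (SE ≈ 0.006) against an oracle computed
  from 10⁶ regime-simulated persons; the conventional time-varying
  comparator (bias ≈ −0.17, toward the null) is fit on the leading 200
  replicates, where its bias is already unambiguous.
- **Null coverage**: 200 replicates with the direct effect switched off;
  the current-exposure CI covers HR 1 ≥ 90% of the time. Coverage is
  assessed on the current-exposure coefficient because the sustained
  contrast retains the mediated pathway and is not null under this
  parameterization.

## Known limitations and numerical choices

- Weight truncation trades positivity-driven variance for confounding
  bias; under strong confounding the (10, 90) truncation visibly pulls the
  estimate toward the crude one. Stability under truncation is therefore a
  meaningful diagnostic only when weights are already near 1, and the test
  suite evaluates it in that regime.
- The time-fixed Cox comparator classifies exposure as ever/never over
  follow-up and is severely biased in these data (immortal-time-like
  structure); it is included as the conventional benchmark, not as a
  usable estimator.
- The anxiety-related comorbidity class (F40–F43) contains the
  cohort-defining PTSD code; the index claim itself is excluded from
  covariate flags, and the comorbidity-exclusion reanalysis ignores the
  index code when dropping persons, since otherwise it would empty the
  cohort.
- Administrative censoring is treated as noninformative; no
  censoring weights.
- All fits use double precision; determinism is guaranteed by a single
  master seed with named per-table RNG streams, and `run_pipeline` writes
  byte-identical summaries for identical configurations.
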