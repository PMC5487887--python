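# Methods

## The problem

Measuring disease incidence normally requires a cohort followed over time.
In many settings — Pacific-island type 2 diabetes surveillance being the
motivating case — only irregularly spaced cross-sectional risk-factor
surveys exist.  This package estimates annual incidence from such serial
prevalence surveys with the birth-cohort method introduced for tuberculin
surveys (the Stýblo annual-risk-of-infection method), adapted to a chronic,
effectively irreversible condition defined by a biomarker threshold
(fasting plasma glucose ≥ 7.0 mmol/L and/or medication use).

## The estimator

Prevalence cells are arranged on a Lexis grid: sex × 5-year age group
(25–29 … 60–64) × survey year, each band represented by its midpoint age
ā (27, 32, …, 62).  A cell (ā, t) belongs to birth cohort b = t − ā.  The
model assumes the annual probability of *not* acquiring the condition,
q(t) = 1 − h(t), is log-linear in calendar time and common across the ages
a cohort lives through.  Then, per sex and age group:

1. **Mean annual disease-free probability.**  With exposure E = ā −
   onset-age years, the observed prevalence P implies the geometric-mean
   annual survival over the cohort's life, q̄ = (1 − P)^(1/E).
2. **Secular trend.**  ln q̄ is regressed on survey year by ordinary least
   squares within each age group; the slope β is the trend of ln q.
3. **Current-year incidence.**  q̄ is centred (E − 1)/2 years before the
   survey, so the survey-year disease-free probability is
   q_t = (1 − P)^(1/E) · exp(β (E − 1)/2), and incidence is i = 1 − q_t,
   reported per 1000 person-years.  Negative estimates — possible under
   sampling noise or a strongly positive β — are revised to zero and
   flagged.

When ln q(t) = c + d·t exactly (age-constant, log-linear), the three steps
invert the cohort survival product *exactly*: (1/E) ln(1 − P) =
c + d·t − d(E − 1)/2, the OLS slope is d, and q_t = exp(c + d·t) = 1 − h(t)
to machine precision.  This identity is the backbone of the test suite's
oracles.  When the hazard varies with age, the estimator returns a
trend-corrected lifetime geometric mean instead of the age-specific rate;
the synthetic generator exposes age multipliers so this bias can be probed
deliberately, but the default test surfaces honour the model's own
assumption.

**Choices made where the method description is open.**  The
"mathematically convenient transformation" is taken as the natural log of
q̄; the current-year correction uses the mid-exposure lag (E − 1)/2; the
representative age of a band is its midpoint; the trend OLS is unweighted
across surveys (a sample-size-weighted option exists).  Each choice is
validated by the exact-recovery oracle rather than asserted.  The
risk-onset age is configurable: 0 ("from birth") is the library default;
the packaged study configuration uses 20, since adult onset both reflects
the epidemiology of type 2 diabetes and produces the observed secular
pattern (prevalence from a few percent early to >20% late).  Estimator
and generator must agree on the onset age; the exposure exponent is
E = ā − onset-age.

## Survey weighting and summaries

Records are eligible if aged 25–64, non-pregnant and with confirmed
fasting status; records with neither a glucose value nor a medication flag
have indeterminable status and are excluded from denominators (counted,
never silently dropped).  Case weights post-stratify each survey to the
nearest previous census jointly over region × sex × 5-year age group:
w = census share / survey share.  Unsampled census strata are surfaced as
uncovered, not imputed.  Two surveys fielded in the same year are pooled
by weighting each to its own census and stacking the weighted records.

Confidence intervals are the textbook binomial normal approximation
p ± z√(p(1−p)/n) on the unweighted cell n, truncated to [0, 1]
(Clopper–Pearson available behind `method="exact"`).  Age standardization
is direct: Σ wₐ rₐ with the reference age distribution taken from a census
(the packaged reference year is the most recent one).  Cumulative risk
over 25–64 is [1 − exp(−x)]·100.  The default accumulation rule
(`as_published`) takes x = Σ rₐ/1000 — one annual rate per band — because
that rule reproduces the published Samoan cumulative-risk rows (e.g.
women 1978 → 2.33%, men 2013 → 7.30%) whereas the textbook person-years
form x = Σ rₐ·nₐ/1000 with nₐ = 5 does not; both modes are provided and
the discrepancy is deliberately left visible.  Incident counts are
rate/1000 × population, rounded half-up only at the reporting boundary.

## Age-period-cohort deviance analysis

Incident counts per stratum (derived as rate × population) are modeled by
Poisson GLMs with a log person-years offset and categorical 5-year terms:
null → age → age + period, and null → age → age + cohort.  Period and
cohort are never entered jointly (age + cohort = period makes the joint
model unidentifiable).  The object of interest is the ladder of deviance
drops, mirroring how such analyses report period versus cohort influence.

## Conway–Maxwell Poisson projection

Counts derived from smoothed rates vary less than Poisson — which is
exactly why a two-parameter count model is needed.  The CMP distribution
P(Y=y) ∝ λ^y/(y!)^ν has dispersion ν (ν = 1 Poisson, ν > 1
under-dispersed).  The regression models

    log λ = β₀ + β_sex + β_age(group) + β_BMI · (BMI − 30)
    log ν  = γ₀ + γ₁ · (BMI − 30)

by full maximum likelihood with analytic gradients (the score needs E[Y]
and E[log Y!] under each cell's fitted distribution; all series work is in
log space with an explicit geometric tail bound, default truncation
tolerance 1e-12).  The log link on ν keeps it positive.  Survey year is
not a covariate: mean BMI carries the secular trend (they are collinear).

**Dispersion degrees-of-freedom correction.**  The profiled ν̂ is biased
upward by ≈ n/(n − p) because the p mean parameters absorb residual
variation — the exact analogue of the MLE variance estimator's bias — and
β̂ inherits the bias through the sharply identified ratio β/ν (the mean
structure satisfies log E[Y] ≈ x'β/ν).  The fit therefore rescales ν̂ and
β̂ by (n − p)/n by default, as GLM software scales dispersion estimates by
residual degrees of freedom.  Simulation at the study's 112-stratum scale
puts the median bias of β_BMI within ~2% with the correction, against
~+11% without it.  `dof_correction=False` restores the raw MLE.

**Scenarios.**  Projection replaces each stratum's mean BMI according to a
rule — follow the secular trend to an externally supplied horizon BMI,
freeze at the baseline year, or shift by Δweight/height² for Δweight ∈
±1…4 kg — and converts predicted counts to age-standardized rates per
1000 using horizon populations.  Intervals are delta-method intervals from
the MLE covariance, propagated numerically through the standardization;
they are model-based and labelled as such.  The horizon-BMI target under
the trend rule is a configuration input, not recomputed here.

## The synthetic generator

Because the original survey microdata are not deposited, a generator
stands in, with fully known truth.  Individuals are simulated per sex ×
birth cohort; disease onset follows annual Bernoulli trials against a
`HazardSurface` (piecewise-constant over 5-year age groups, log-linear in
period on the survival scale), status is absorbing, and everyone is
disease-free at birth.  Surveys draw individuals by per-stratum sampling
fractions, returning unit records plus the true census table; fraction 1.0
returns the population itself, making the weighted-prevalence-equals-truth
check exact.  Glucose values never straddle the case threshold ambiguously:
non-cases draw FPG in [4.0, 6.9], untreated cases ≥ 7.0, and treated cases
may sit below 7.0 but carry the medication flag.  There is no excess
mortality among cases by default (the estimator ignores differential
survival); a mortality knob exists to probe that bias, as do hazard age
multipliers and knobs for pregnancy and unconfirmed fasting.

Default study conditions: eight surveys over 1978–2013 (1978, 1991 ×2,
1995, 2002, 2003, 2010, 2013; the 1991 pair is pooled downstream), four
census regions with fixed shares, base hazards 14.5 (men) / 13.5 (women)
per 1000 at 2013 with survival-scale slope −1.7e-4 per year (valid across
every exposure year the oldest 1978 cohorts live through), risk-onset age
20.  That yields prevalence from ≈5% (young, 1978) to ≈35% (old, 2013) and
standardized incidence roughly doubling — the secular pattern being
emulated.  Mean BMI rises 0.11 kg/m² per year to 30.9 (men) / 34.4 (women)
in 2013 — implied by mean 2013 weights of 93.6/90.7 kg at heights
1.74/1.62 m — with an age gradient of 0.08 kg/m² per year of age and
individual noise (SD 4).

What the generator does *not* emulate: household/cluster sampling
correlation, non-response, measurement error in FPG, diagnosis-method
differences between surveys, migration, or competing mortality.  Passing
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions plus sampling noise — not robustness to every
real-world violation; the knobs above exist to explore the latter.

## Numerical choices and problem sizes

- Trend OLS via `numpy.linalg.lstsq`; a two-point fit is exact.
- Cells with P = 1 (q̄ = 0) are excluded from the log-trend fit and
  flagged; fewer than two usable survey years in a group degrades to
  β = 0 with a warning rather than failing the whole surface.
- CMP series: shared truncation grid per batch, sized from the mode
  λ^(1/ν) plus 15 standard deviations, hard cap 20,000 terms, geometric
  tail bound checked against the 1e-12 tolerance; ν = 0 with λ ≥ 1 is
  refused (divergent).
- CMP optimization: L-BFGS-B with analytic gradients from a Poisson-GLM
  start (BFGS fallback), covariance from a central-difference Hessian.
- Interpolation between surveys is linear on the rate scale, exact at
  knots; extrapolation is refused outside the survey span (projection is
  a modelling step, not interpolation).
- Rounding (half-up) happens only at reporting boundaries.

Test-suite problem sizes are chosen to keep the full run to a few minutes:
populations of 60–400 individuals per birth cohort, surveys of ~400–1500
records, 20–50 replicate seeds for the expectation-level checks, 200
replicate fits for the CMP recovery benchmark, and a 20,000-draw sampling
check for the CMP moments.

## Known limitations

- With age-varying hazards the estimator recovers a trend-corrected
  lifetime geometric mean, not the age-specific rate; interpret
  age-specific output under that assumption.
- The binomial intervals ignore the design effect of weighting and the
  uncertainty of the trend fit; scenario intervals condition on the
  Stýblo stage (no error propagation from prevalence estimation into the
  projection CIs).
- The published cumulative-risk accumulation rule differs from the
  printed formula; the package defaults to the rule the published rows
  actually satisfy and documents the alternative.
- One published summary cell (men 1978 cumulative risk) is not
  reproducible from its own printed row under either rule — consistent
  with its pre-clamp negative rate having been used — and is excluded
  from validation.
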