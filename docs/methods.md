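# Methods

This note documents the statistical content of `pxmode`: the models it
fits, the synthetic-data generator it validates them against, the numerical
choices, and what the tests do and do not establish.

## Estimand

The target is the population mean difference in the 0–100 patient
experience score between mobile-web and telephone administration,
Δ = E[Y(mobile)] − E[Y(telephone)], over all randomized patients — not only
respondents. Randomization identifies the arm contrast; nonresponse does
not, unless missingness is ignorable given observed covariates (MAR: score
distributions of respondents and nonrespondents coincide within each
stratum of mode × sex × age group × field of care × hospital).

## Scoring

Six domains partition the 21 items (nurse Q1–Q4, doctor Q5–Q8, medication
and treatment Q9–Q13, hospital environment Q14–Q15, patient's rights
Q16–Q19, overall ratings Q20–Q21). Each item is rescaled to a 100-point
maximum: Likert 1→0, 2→100/3, 3→200/3, 4→100; Q13 yes→100 / no→0; Q20–Q21
v→10·v. Domain and total scores are means of member item scores, which is
the rescaled sum. The Likert anchor (minimum category = 0 rather than 25)
is a deliberate choice: it is the only affine map giving all three formats
a common 0 floor and 100 ceiling. It is isolated in `rescale_item` so an
alternative convention can be swapped without touching anything else. Only
complete responders are scored; partial records raise a validation error
rather than receiving partial-domain scores.

## Estimators

**Unadjusted.** Difference of respondent arm means with the Welch
(unequal-variance) t: the two arms' score SDs genuinely differ, and Welch
is the safe default when homoskedasticity is not assumed.

**IPW.** Response propensity π̂ from a maximum-likelihood logistic
regression of the response indicator on main effects of arm and the four
stratification factors (reference coding, first level alphabetically —
estimates are invariant to coding; the fixed rule only serves
reproducibility). The contrast uses Hájek (normalized) weighting within
each arm, which makes it invariant to rescaling all weights. The standard
error is the stacked M-estimation sandwich over the logistic score
equations and the two weighted-mean estimating equations, so the
uncertainty of the estimated weights is propagated; the CI uses the normal
reference, as the sandwich is asymptotic. Separation (a factor level with
all-or-none response) and rank deficiency are detected and reported as
errors naming the offending factor.

**MI.** Within each arm separately, a Bayesian linear regression of the
observed score on strata main effects with the noninformative prior:
per copy, σ² is drawn from RSS/χ²(n−k), coefficients from
N(β̂, σ²(XᵀX)⁻¹), and missing outcomes as posterior-predictive draws.
Per-arm models (rather than one pooled model with an arm term) follow from
the MAR statement conditioning on mode and from the delta shifts being
arm-specific. Predictors are the strata main effects, not the 64-cell
saturation — respondent counts per cell are too small to saturate.
Per-copy arm-mean differences over all randomized patients are pooled by
Rubin's rules, T = W + (1 + 1/m)B, with the classical degrees of freedom
(m−1)(1 + W/((1+1/m)B))²; the Barnard–Rubin small-sample correction is
omitted because n ≫ m throughout. When B = 0 (nothing was imputed) the
reference collapses to the normal; B = W = 0 is reported as degenerate.
The default m = 50.

**Subgroups.** Estimates within levels of sex, age group, and field of
care (the subgroup variable is dropped from the propensity/imputation
predictors in the restricted fits). Interaction p-values come from a Wald
test of the arm×variable terms in a linear outcome model: on respondents
(unadjusted); weighted with an HC0 robust covariance treating weights as
fixed (ipw) — a pragmatic simplification of the full stacked sandwich;
or fit per imputed copy and pooled multivariately by the D1 statistic with
Li–Raghunathan–Rubin degrees of freedom (mi).

**Sample size.** Smallest per-group n for a two-sided two-sample t-test,
iterating the exact noncentral-t power function upward from the normal
approximation. For a 1-point difference, SD 2, 80% power, α = .05 this
gives 64 per group (the normal approximation gives 63).

## Delta adjustment and tipping

The MNAR sensitivity model is a pattern mixture: nonrespondents' mean
scores are assumed shifted by δ₁ (telephone) / δ₂ (mobile web) points
relative to comparable respondents. Implementation: the MI machinery adds
the arm's delta to every imputed value, so δ₁ = δ₂ = 0 reproduces the MAR
analysis bit for bit with the same seed. The grid (default
δ ∈ {−5, −2.5, 0, 2.5, 5} per axis, a 2.5-point step inside the range the
sensitivity analysis is meant to cover; plausibility window ±10) reuses
one seed across cells. Because the shift is additive and applied after the
base draws, the point estimate obeys exactly

    Δ̂(δ₁, δ₂) = Δ̂(0, 0) + δ₂·f_mob − δ₁·f_tel,

with f the arm's missing fraction. The tipping boundary reports adjacent
grid cells straddling zero (and straddling the change in 95%-CI exclusion
of zero) plus the interpolated zero crossing from the identity. Imputed
values are deliberately **not** clipped to [0, 100] by default: clipping
would break the linear identity that both the validation and the
interpolation rely on; a `clip=True` flag exists for users who prefer
bounded imputations.

## Synthetic trial generator

The generator is the test bed standing in for individual-level data that
is not publicly available. It emulates:

- **Strata**: sex × age group × field of care × hospital drawn
  independently with marginal probabilities matching the published
  randomized denominators. The joint distribution of the real cohort is
  unknown (only margins are published), so independence is assumed.
- **Response**: Bernoulli with a main-effects logit on arm + strata. The
  calibrated coefficients are a weighted least-squares fit to the 24
  published level×mode response-rate margins with the two arm totals
  up-weighted; a main-effects model cannot reproduce every margin (the
  published rates reverse between arms in the oldest age group, which
  requires an interaction), so arm totals are matched closely (expected
  22.2% / 32.6% vs 22.4% / 32.5%) and level margins approximately. This
  mirrors the form of the downstream propensity model, so IPW is correctly
  specified in the recovery studies.
- **Outcome**: latent total = intercept + stratum effects + arm effect +
  Gaussian noise, clipped to [0, 100]. Stratum effects are fixed plausible
  values (older patients score higher, small sex/care-field effects,
  modest hospital spread); the intercept, arm effect, and per-arm residual
  SDs are solved so the analytic respondent mean and SD per arm (censored
  normal moments, respondent-weighted across cells) equal the published
  84.92 (14.34) / 81.51 (16.35). Matching both arms' SDs requires arm-
  specific residual SDs. On the clipped scale, the population contrast is
  smaller in magnitude than the latent arm effect; `true_estimand` returns
  the exact observable-scale contrast and is what recovery tests target.
- **MNAR**: nonrespondents' outcomes are shifted additively by the arm's
  true (δ₁, δ₂) before being discarded — exactly the delta-adjustment
  model, so the grid cell at the true shifts is a consistent estimator of
  the estimand and recovery is well-posed.
- **Items**: each respondent's 21 raw responses are synthesized from the
  latent total by adding a small symmetric uniform perturbation (halfwidth
  5 points, shrunk near the boundary so the value stays in range) and then
  *stochastically rounding* to the item's legal grid. Stochastic rounding
  is exactly unbiased, so the computed total equals the latent total in
  expectation, with ~2.5–3 points of item-discretization noise. Simulated
  respondent SDs therefore run ~0.2 points above the analytic targets.

Seeding: one master seed; per-arm and per-stage child streams are spawned
deterministically, so the same config is byte-identical and a change in
one stage does not perturb the draws of another.

**What the generator does not emulate**: the real joint strata
distribution; response-by-strata interactions; item-level response styles
(acquiescence, extreme responding, social desirability) that differ by
mode — in this generator the mode effect is a pure location shift; domain
scores share one latent, so per-domain means are not separately
calibrated; call-attempt/contact dynamics. Passing recovery tests
therefore shows the estimators are correct *under their assumed models*,
not that the MAR assumption holds in any real survey — which is exactly
why the delta-adjustment analysis exists.

## Problem sizes used in validation

Recovery and coverage studies run at the calibrated design size (1600 per
arm) with m = 10 imputations per replicate — 400 MAR replicates for
bias and 95%-CI coverage (accepted band 92–98%), 200 MNAR replicates for
delta-adjusted recovery and the predicted MAR bias, and 600 null
replicates for the interaction test's type-I error (accepted band 3–7% at
α = .05); m = 10 keeps replicate cost low while leaving Rubin pooling
nondegenerate. The linearity identity is asserted at m = 50 on the full
grid. These sizes give Monte-Carlo standard errors a few percent of the
quantities tested.

## Known limitations

- The IPW interaction test treats weights as fixed in its robust
  covariance; only the main IPW contrast carries the full stacked
  sandwich.
- The imputation model is linear in strata main effects on the clipped
  scale; clipping induces tiny interaction terms the model ignores
  (well under 0.1 points at the calibrated parameters).
- The sandwich SE is asymptotic: on fixtures of a few dozen records it can
  differ from a jackknife by tens of percent; the two agree within a few
  percent by n ≈ 300.
- `ground_truth` reports the latent-scale arm effect and the MNAR shifts;
  for observable-scale comparisons use `true_estimand`, which accounts for
  clipping.
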