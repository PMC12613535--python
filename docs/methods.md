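# Methods

This package implements the design and analysis machinery for a two-arm,
multi-site, double-blind, placebo-controlled superiority trial of combined
inhaled epinephrine and oral dexamethasone (the "EpiDex" combination) in
infants presenting to the emergency department (ED) with bronchiolitis.  The
primary endpoint is hospitalisation for bronchiolitis within 7 days (168 h)
of enrolment.  Because no participant-level data are distributed, a
synthetic-cohort generator is a first-class component: every analysis stage
is exercised and validated against data whose truth is known.

## Outcome definitions

Hospitalisation is any of: (1) admission to an inpatient ward; (2) an ED
length of stay (LOS) of 12 h or greater; (3) a combined ED and
observation-unit LOS of 12 h or greater.  The 12-h boundary is inclusive.
The enrolment-visit LOS clock starts at the first study medication, or at
consent when no study medication was received, and ends at discharge from
the ED or observation unit.  Return-visit stays are clocked from the earlier
of triage and registration.  Caregiver-reported admissions and ED visits at
study hospitals count only when confirmed on medical-record review; at sites
with administrative-database access the same applies to non-study-hospital
reports, and at sites without it the caregiver's report is used as-is.
Matched caregiver reports are treated as confirmations of the record event,
not additional contacts, so visit counts are not inflated by double
reporting.

Conventions the endpoint definitions leave open, fixed here:

* a stay *starting* inside a window qualifies even if the 12-h threshold is
  crossed beyond it (a return stay beginning at 167 h that reaches 12 h at
  179 h counts toward the 7-day outcome);
* return-ED intervals separated by at most 1 h are merged into one
  combined stay before the 12-h test (the definitions do not define
  contiguity);
* an admission at the enrolment visit is bronchiolitis-related by
  definition, as is the enrolment ED stay; return-visit stays count toward
  bronchiolitis-cause outcomes only when coded as bronchiolitis;
* a death truncates observation windows: binary outcomes not already
  positive are flagged missing rather than false, and the same rule covers
  loss to follow-up before a window closes.  Missing outcomes are never
  imputed anywhere in the pipeline.

## Inference model

All binary endpoints use Bernoulli regression with a log link, so
exponentiated coefficients are risk ratios:

    log p_i = beta0 + theta * arm_i + u_site(i),   u_s ~ N(0, sigma_u^2)

with variants adding a subgroup main effect and treatment-by-subgroup
interaction, or patient random intercepts for the repeatedly measured
symptom-resolution outcome.  The active arm is declared superior when the
posterior probability that theta < 0 exceeds 0.99 (strictly; the threshold
is configurable).  Effects are reported as the posterior mean risk
difference (placebo minus active) and relative risk with 95%
highest-density intervals (HDIs); in hierarchical fits the per-draw arm
risks are averaged over sites weighted by observed site frequencies, i.e.
reported on the population-averaged scale.

Sampling is by an adaptive random-walk Metropolis-within-Gibbs written for
this package: data are collapsed to sufficient statistics per covariate
pattern, fixed effects update one scalar at a time, random effects update as
a conditionally independent vector block, and the random-effect SD moves on
the log scale under a half-normal prior.  Proposal scales adapt during
warmup only (Robbins–Monro, target acceptance 0.44 per scalar).  The
log-binomial support constraint (fitted probability ≤ 1 at every observed
covariate pattern) is handled exactly: any proposal violating it has
log-likelihood −∞ and is rejected, so no retained draw implies a
probability above one.  Convergence is monitored with split-chain R-hat and
effective sample size (via arviz); R-hat above 1.01 attaches a warning to
the fit.

For the plain two-arm model with uniform or Beta priors on the per-arm
risks, `(beta0, theta)` is a smooth reparameterisation of `(p0, p1)` and the
posterior is exactly a product of Beta distributions (the prior is stated on
the risk scale and carries the Jacobian).  This conjugate path is exposed as
`method="conjugate"`; it is draw-for-draw the same posterior and is used
inside design and calibration loops.  The MCMC path is validated against it
(posterior means and HDI endpoints within Monte-Carlo error on fixed
datasets) and by simulation-based calibration: over 200 prior→data→posterior
replicates the rank of the true log RR among thinned posterior draws is
uniform (chi-square test).

### Priors

The study's treatment-effect prior came from an expert elicitation that is
not reproduced here; `PriorSpec` therefore requires the user to supply one.
The shipped `elicited_like_prior()` is a clearly labelled stand-in —
independent Beta priors on the per-arm risks with means 0.35 and 0.27 and
caller-chosen effective sample sizes (default 40) — and is not the study
prior.  "Minimally informative" defaults are normal(0, 10²) on regression
coefficients and half-normal(1) on the site SD.  A normal prior on the log
RR (`normal_logrr`) is also supported; whether an informative prior should
sit on the RR scale or on joint per-arm risks is left open deliberately —
both are available.

### Time-to-event and cost models

The uncensored length-of-stay outcomes use a proportional-hazards model with
a piecewise-constant baseline hazard on quantile-based cut points (default
8 intervals), fitted by the same sampler through the standard
counting-process (Poisson) likelihood; the median hazard ratio and 95% HDI
are reported.  This replaces a Laplace-approximation Cox fit with an
equivalent fully sampled model.  With one interval and near-flat priors the
posterior matches the conjugate gamma–exponential form, which the tests
exploit as an oracle.  Out-of-pocket expenses use a Bayesian location model
(normal family; lognormal or gamma when residual skewness — reported with
every fit, flagged above |skewness| = 1 — indicates it), reporting a mean
difference or ratio-scale effect.

## Design calculations

**Sample size (average length criterion).**  For each candidate per-arm n,
per-arm risks are drawn from the design prior, binomial data simulated, and
the 95% HDI length of the risk-difference posterior computed from conjugate
Beta posteriors; the selection is the smallest n whose prior-predictive
average length falls below the criterion (0.09).  The study values are 1500
outer replicates and 5000 posterior draws per study ("5000 simulations" is
read as the posterior draw count; configurable).  A point-mass design prior
is analysed under the uniform reference prior (a point-mass posterior would
be degenerate); in that case the selection tracks the closed form
n ≈ (2·1.96/L)²(p₀q₀ + p₁q₁).  The selected n is inflated for attrition by
ceiling division — 410 analysable per arm at 5% loss gives recruitment
targets of 432 per arm, 864 total.

**Operating characteristics.**  Type I error and power of the 99% rule are
estimated by simulating trials at fixed true risks (0.35/0.35 for the null;
0.35/0.27 at the target difference of 8 percentage points) and running the
two-arm analysis via the conjugate path (a site-hierarchical MCMC variant
exists for reduced simulation counts).  The trial's published 4.1% / 81%
figures depended on the unavailable elicited prior and an unstated model
choice, so they are not asserted; the properties checked instead are the
flat-prior error rate (≈1%, consistent with a one-sided 0.01 rule), a steep
power gradient in the effect size, and monotonicity of power in n.

## Synthetic cohort

The generator emulates: site-stratified permuted-block 1:1 allocation
(block size configurable, default 4, even only — odd blocks cannot split
1:1); twelve sites with Dirichlet-free configurable weights, a quarter in
the southern hemisphere and half with administrative-database access;
baseline covariates (age uniform on 60–365 days, sex-specific weights,
respiratory-severity score, atopy/smoke/feeding history, virus type)
drawn independently with documented defaults; a log-link outcome model
congruent with the analysis model (baseline log risk log 0.35, treatment
log RR log(0.27/0.35), site SD 0.15, centred covariate effects), with
probabilities clamped to [1e−6, 1−1e−6] and a warning when more than 1% of
draws clamp; enrolment-visit clocks and follow-up events constructed so
that deriving the primary outcome reproduces the latent truth table
exactly; caregiver-survey duplicates and unconfirmable reports to exercise
the confirmation rules; loss to follow-up, withdrawals, missingness
(completely at random or covariate-dependent with a calibrated marginal
rate) and protocol deviations (missed medications, doses outside ±5%,
timing errors, missed second dexamethasone dose).  An optional
`log_rr_risk_slope` makes the individual treatment effect depend on the
covariate linear predictor, giving a known effect gradient for
heterogeneity-recovery tests.

A single master seed drives fixed-key child streams per component, so runs
are byte-reproducible and adding a component never perturbs earlier draws.

What the generator does **not** emulate: covariate correlation (independence
by default, with a dependence hook), seasonality and recruitment calendars,
informative site-by-treatment interactions, measurement error in clocks, or
real coding noise in causes of admission.  Passing tests therefore
demonstrate internal correctness of the estimators and decision rules under
the stated data-generating assumptions, not robustness to real-world
violations of them.

Because covariate and site effects enter multiplicatively on the risk scale,
the marginal control-arm risk sits slightly above the configured baseline
(log-scale convexity); tests that check marginal risks switch heterogeneity
off.

## Subgroups and heterogeneity of treatment effect

Six pre-specified subgroups: age < 6 months (operationalised as 183 days),
first respiratory symptoms within 48 h of enrolment (boundary inclusive),
personal eczema, family atopy, hemisphere (from site metadata), and
nebuliser vs MDI-s delivery.  Each is analysed with main effects for
treatment and subgroup plus their interaction; a positive (negative) effect
is declared only when the interaction exceeds (falls below) zero with
posterior probability above 0.99.  Participants missing a defining covariate
drop out of that subgroup model only.  Under a zero-interaction generator at
cell event counts of ~150+, the declaration rate is ≈2% (two 1% tails) and
the posterior tail probability is uniform; at materially smaller cell counts
(~60 events) the skew of the log-risk posterior makes the rule mildly
anti-conservative (measured ≈4–5%) — a known small-sample limitation of
tail-probability declarations, not corrected for because the rule is fixed
by design.

The HTE analysis fits a multivariable logistic risk model (age, sex,
prematurity, illness duration — kept continuous in hours — previous
wheezing, eczema, family atopy, household and prenatal smoke, breastfeeding,
virus type) by weakly penalised maximum likelihood, with the treatment arm
excluded by construction (permutation invariance is asserted at run time).
The risk model is deliberately frequentist: only the within-stratum
treatment effects are Bayesian.  Participants are split at the deciles of
predicted risk into ten strata (stable enrolment-order tie-break; fewer
distinct values than strata triggers a merge warning), and within each
stratum the unadjusted two-arm relative-risk posterior is reported as a
median RR with 95% HDI.  Strata with a single arm represented are reported
as inestimable rather than dropped.

## Missing data

Per-variable, per-arm missing proportions are reported with denominators of
randomised, non-withdrawn participants.  Below 5% missingness the analysis
is complete-case; at exactly 5% or above ("below 5%" read strictly) the
baseline characteristics of participants with and without missing values
are compared descriptively (standardised mean differences, no tests; |SMD| >
0.2 flagged) before deciding.  The gate is applied per variable, with a
whole-dataset summary alongside.  When complete-case analysis is not
defensible for a missing covariate, a joint Bayesian model is fitted using a
selection-model factorisation: the log-link outcome model including the
covariate, a Bernoulli prevalence model for the covariate, and a logistic
model for the missingness indicator which may depend on the covariate's own
value and on the observed outcome.  Missing covariate values are imputed
inside the Gibbs sweep from their exact full conditional (collapsed over
observation patterns for speed).  Under 20% completely-at-random
missingness the treatment-effect posterior matches the full-data fit within
Monte-Carlo error; under missingness driven by the covariate and outcome,
the joint model removes most of the complete-case bias.

## Reporting

Three nested analysis populations: intention-to-treat (randomised, primary
outcome available, consent not withdrawn); per-protocol (additionally
eligible, both epinephrine treatments with correct timing — operationalised
as the second dose 30 ± 15 min after the first, the schedule being stated
but the tolerance not — and dexamethasone within ±5% of the 0.6 mg/kg dose
capped at 10 mg); and restricted per-protocol (additionally requiring the
second dexamethasone dose unless admitted within the 40-h second-dose
window, anchored at the first dose).  Baseline tables are purely
descriptive: categorical variables as n (%), continuous as mean (SD) when
|sample skewness| ≤ 1 ("sufficiently normal" needs an operational rule;
this one is configurable and recorded per variable in the output), else
median (IQR).  Flow counts (screened, eligible, excluded by reason,
randomised, treated, lost, discontinued, analysed, withdrawals by reason and
arm) are internally cross-checked and inconsistencies are hard errors.
Safety events are counted at most once per participant per outcome on ITT
denominators; adverse-event and organ-class codes are carried as opaque
strings (no dictionary coding).

## Problem sizes and numerical choices

Reported analyses default to 4 chains × 1000 draws after 1000 warmup
iterations; simulation loops (operating characteristics, calibration
studies, per-stratum fits) use single short chains or the exact conjugate
path, which is what keeps the full validation suite at a few minutes on one
CPU.  Calibration studies run at 200 replicates, recovery studies at 50;
operating characteristics use 2000 simulated trials with 8000 posterior
draws each.  HDIs are the shortest window over sorted draws (≥100 draws
required); clearly multimodal draw sets still return the shortest contiguous
interval with a note.  Ties in risk-decile assignment break by stable
participant order.  Degenerate inputs are explicit errors: odd block sizes,
improper priors in prior-predictive averaging, identical event times in the
hazard model, zeros under a lognormal cost model, fully missing covariates.

## Known limitations

* The expert-elicited prior is unavailable; published operating
  characteristics that depend on it cannot be, and are not, reproduced.
* The declaration rule's mild small-sample anti-conservatism (above).
* The piecewise-exponential hazard model is an equivalent-likelihood
  substitute for the Laplace-approximated Cox fit, not a re-implementation.
* The generator's independence and stationarity assumptions above; economic
  (cost-effectiveness) analysis and 18-year follow-up outcomes are out of
  scope, as are adverse-event dictionary coding and monitoring governance.
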