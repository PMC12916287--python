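# Methods notes

## Scope and data model

The package implements a complete desk-scale analysis chain for
developmental trajectories of depressive symptoms: questionnaire scoring,
latent-class trajectory estimation, a staged model-selection framework,
and downstream association analyses (risk-ratio regression for clinical
outcomes; empirical-Bayes moderated linear models for biomarker panels).
Input is long-format longitudinal data (subject, age, 13 item responses
per occasion), a subject-level covariate table, an outcomes table, and a
subjects × analytes biomarker matrix with analyte metadata.  Real cohorts
of this design are managed-access, so a synthetic-cohort generator is a
first-class module and defines the conditions under which every estimator
is validated.

## Questionnaire scoring

Each of the 13 items is scored 0/1/2 (total 0–26).  Occasions missing one
or two items have those items imputed to the median of the answered items
(mean of the two central values for an even count), with the total
rounded half-up; occasions missing three or more items are unscorable by
default.  The boundary case of exactly three missing items is not covered
by the stated scoring convention ("fewer than three" imputed, "more than
three" missing); we resolve it conservatively as unscorable — imputing
23% of an instrument is hard to defend — and expose `max_missing` for the
permissive reading.  Fractional (unrounded) totals are available via
`round_total=False`.  Subjects need at least three scored occasions to
enter the model-fitting sample; everyone with at least one scored
occasion still receives predicted class membership afterwards.

## Trajectory mixture models

For subject *i* with score vector *y_i* and fractional-polynomial design
*X_i* built on transformed age, the marginal log-likelihood is

    l = sum_i log sum_g pi_g N(y_i; X_i b_g, V_ig),
    V_ig = omega_g^2 tau^2 J + sigma^2 I.

`random_effects="none"` (GBTM) sets tau = 0; `"common_intercept"` uses a
shared random-intercept variance tau^2; `"class_proportional_intercept"`
scales it per class with omega_1 = 1 fixed for identifiability.  Residual
variance is common across classes (the convention of the reference
implementations in this area; class-specific variants are out of scope).
The per-subject Gaussian density uses the Sherman–Morrison closed form of
V, so no matrix factorisations are needed.

Age is transformed as t = age/10 (equivalently (age−10)/10 + 1), mapping
the design range 10–25 years onto [1, 2.5] so that every fractional
power, including logs and negative powers, is well conditioned.  The
transform is configurable per basis.

**Estimation.**  GBTM is fitted by EM with closed-form M-steps (weighted
least squares per class, pooled residual variance).  The EM objective is
monitored; a decrease beyond 1e-8 relative is raised as an error rather
than papered over.  The random-intercept variants are fitted by direct
quasi-Newton (L-BFGS) on the marginal likelihood with softmax-parameterised
mixing proportions and log-parameterised variance components.
Convergence is declared at a relative log-likelihood change below 1e-6
(up to 500 final iterations); exhausting iterations returns
`converged=False` instead of raising.

**Multistart.**  50 random starts run for 10 iterations; the best
continues to convergence.  Start values are "exemplar" starts: each class
start is a ridge-stabilised OLS fit to one randomly chosen subject's own
occasions.  We first implemented the more common scheme of perturbing a
single-class OLS fit with noise scaled to its coefficient standard
errors, but on four-class cohorts it collapsed classes or stalled in
local optima at any perturbation scale we tried, whereas exemplar starts
located the global optimum reliably; the perturbation scheme remains
available via `start_method="perturb_ols"`.  All stochastic steps are
seed-controlled and refitting with the same seed is bit-reproducible.

Classes are reported in descending order of estimated mixing proportion,
and modal assignment breaks ties toward the lowest class index.

## Model selection

Fit indices: BIC = −2l + k log N with N the number of *subjects*;
relative entropy 1 − EN/(N log G) with EN the total classification
entropy (defined as 1 for G = 1); ICL in the ICL-BIC convention
BIC + 2·EN — several ICL definitions circulate, and the hard-assignment
variant is available behind a flag; average posterior probability (APP)
per modally assigned class; odds of correct classification
OCC_g = [APP_g/(1−APP_g)]/[pi_g/(1−pi_g)].

`select_model` is a pure function of its candidate list: (1) class-number
sweep within one structure, by BIC among converged candidates whose
smallest class holds ≥ 5% of the sample; (2) structure comparison at the
chosen class count under APP ≥ 0.7 and OCC ≥ 5 gates (if no structure
passes, the gates are relaxed and the relaxation is recorded); (3)
fractional-polynomial refinement by BIC.  When BIC and ICL disagree, BIC
decides and the disagreement is logged in the decision trail.  "Visual
inspection" steps are supported by emitted class-curve tables and plots;
they never gate automatically.  The curve tables carry approximate 95%
bands from the within-class responsibility-weighted OLS covariance; the
full mixture information matrix is deliberately not assembled.

## Risk-ratio and continuous-outcome models

Binary outcomes use modified Poisson regression: a log-link Poisson GLM
on the binary response with an HC0 sandwich variance, which targets the
risk ratio directly and avoids the non-collapsibility and convergence
issues of log-binomial fits.  (The marginal-effects route — fit a
logistic model, average predicted risks under counterfactual class
assignment, ratio them — is provided as `estimate_rr_gcomputation` for
parity checks, with an optional percentile bootstrap.)  95% CIs use the
1.96 normal quantile on the log scale.  Continuous outcomes use OLS with
unstandardised coefficients.  Covariate sets: basic = sex, maternal
education, maternal occupational social class; adjusted adds BMI at age
10.  All models are complete-case; the reference class is the largest.
A class with zero events yields a flagged degenerate result, not an
exception.  FDR flags pool the p-values within the results table they
are computed on (per-family pooling is a caller choice).

Sensitivity modes mirror the class-uncertainty checks: restricting to
subjects with modal posterior probability ≥ 0.7, or replacing the class
factor with the G−1 posterior-probability columns (reference omitted).
With crisp posteriors both modes reproduce the primary analysis exactly.

## Biomarker models

Analytes are modelled on their analysis scales: proteins on the delivered
log2 (NPX-like) scale; metabolomic features natural-log transformed when
strictly positive and standardised to SD units (the source convention for
metabolite scaling is not stated; SD units are our default and make
effect sizes comparable across features); blood count / clinical
chemistry natural-log transformed so exponentiated coefficients read as
percentage differences.  Values below the limit of detection among
retained proteins are kept as delivered; LOD/2 substitution is available
behind a flag.  The LOD exclusion threshold (fraction ≥ 0.5 below LOD)
is inclusive.

Per-analyte OLS fits share one design matrix; residual variances s_g^2 on
d_g degrees of freedom are shrunk toward a scaled-inverse-chi-square
prior (d0, s0^2) estimated by the method of moments on
e_g = log s_g^2 − psi(d_g/2) + log(d_g/2):

    psi'(d0/2) = max{0, Var(e) − mean psi'(d_g/2)}      (d0 = inf at 0)
    s0^2       = exp(mean(e) + psi(d0/2) − log(d0/2))
    s~_g^2     = (d0 s0^2 + d_g s_g^2)/(d0 + d_g).

The s0^2 identity follows from E[e] = log s0^2 − psi(d0/2) + log(d0/2);
the Monte-Carlo recovery test (planted d0 = 4, s0^2 = 2) pins the sign
convention.  Moderated t statistics use d0 + d_g degrees of freedom, with
a normal reference when d0 is infinite; `prior_df=0` reproduces ordinary
t-tests exactly.  Blood count/chemistry regressions default to plain
per-analyte models (no moderation), with moderation available.

## Derived clinical indices

HOMA-IR uses the standard Matthews constant: glucose [mmol/L] × insulin
[uU/mL] / 22.5.  The metabolic-syndrome rule counts five risk factors
(waist by sex/ethnicity cut-offs, triglycerides ≥ 1.7, HDL < 1.0,
SBP ≥ 130 or DBP ≥ 85, glucose ≥ 5.6) and is positive at ≥ 3.  With
missing components, a classification is issued only when it is invariant
to every undetermined factor, otherwise "missing"; a man of unknown
ethnicity with waist in [90, 94) cm likewise has an undetermined waist
factor.  Thresholds are externalised and inclusive/strict exactly as
conventionally quoted.

## Synthetic-data generator: what it emulates and what it does not

Defaults encode the emulated design: ten occasions at ages
10, 12, 13, 16, 17, 18, 21, 22, 23, 25; four classes with mixing
proportions (69.6, 13.3, 7.0, 10.0)% normalised onto the simplex (the
published shares sum to 99.9% from rounding); quadratic class curves
fitted to anchor points sketching the four canonical shapes (low flat;
rise-then-fall peaking mid-adolescence; early rise then sustained high;
late rise after ~17).  The anchor values are illustrative — recovery
tests always compare against whatever is planted.

Item generation: the latent occasion value (class curve + optional
subject random intercept + Gaussian residual) is truncated to [0, 26] and
rounded to the intended sum score, which is then spread over 13 items in
{0, 1, 2} in random order.  Scoring the items reproduces the latent sum
exactly; the item-level split carries no signal.  The Gaussian residual
is a stand-in — the real instrument's sum-score distribution is
zero-inflated and right-skewed, and nothing here models item-level
psychometrics.

Noise defaults are residual SD 2.5 score units and *no* subject random
intercept, making the default cohort group-based-trajectory data — the
model family the selection procedure targets.  Two considerations fixed
these values.  First, with a random intercept in the generator a GBTM
BIC sweep provably overextracts (extra classes absorb the unmodelled
between-subject heterogeneity — the same phenomenon reported in the
simulation literature), so GMM-style heterogeneity is opt-in
(`random_intercept_sd > 0`, with per-class multipliers).  Second, the
truncation at score 0 makes the low-stable class non-Gaussian; at
residual SD ≳ 3 this floor effect biases mixture ML estimates of the
class shares by ~3 percentage points, defeating the generator's purpose
as a recovery benchmark.  At SD 2.5 the planted shares are recovered to
well under 1 point while within-class spread remains realistic.

Missingness is MCAR per occasion with response rates declining from 0.95
at age 10 to 0.50 at 25 (attrition-like; expected ~7 of 10 occasions
observed), plus an optional dropout hazard and an optional MAR-on-class
response-odds multiplier (off by default).  Covariates (sex, 5-level
maternal education and occupational social class, right-skewed childhood
BMI, family adversity, deprivation quintile) are drawn from marginal
distributions shaped like the published descriptive tables; adversity and
deprivation are noise covariates, not linked to class.  Not modelled:
sampling weights, consent withdrawal, sibling structure.

Outcomes are drawn with risk = baseline × RR(class) × exp(covariate
terms), validated to stay within [0, 1]; the packaged depression-diagnosis
configuration plants adjusted risk ratios 3.65 / 13.11 / 6.25 for the
adolescent-limited / adolescent-persistent / adulthood-onset classes at
2% baseline risk.  The protein panel is a synthetic 92-analyte
inflammation panel in which 25 analytes are configured above the 50%
below-LOD threshold (so the standard filter retains 67); LODs are placed
at the empirical quantile matching each analyte's target censoring
fraction.  The metabolomic catalogue has the stated 57-feature
composition (9 cholesterol, 12 apolipoproteins/lipids, 3 particle sizes,
16 fatty acids, 3 glycolysis, 8 amino acids, 3 ketones, 2 fluid balance,
1 inflammation) plus an excluded lipoprotein-subclass block; panel
membership names are synthetic stand-ins and only counts, families and
categories matter downstream.

Because the generator is Gaussian-per-class with MCAR missingness,
passing recovery tests demonstrates correctness of the estimators under
the assumed data-generating process; it does not certify behaviour under
real-world features the generator omits (informative missingness,
zero-inflation beyond truncation, panel batch effects).

## Problem sizes used in the validation suite

Class-share and structure recovery run on n = 2000 cohorts (the
selection sweep over G = 1..6 on two seeds; proportion recovery on three
seeds; ten seeds in the acceptance script).  Risk-ratio recovery uses 200
replicate outcome draws at n = 5000 with covariate/class frames refreshed
every 10 replicates.  Likelihood identities are checked against explicit
multivariate-normal oracles on small instances (≤ 10 subjects, ≤ 4
occasions); the empirical-Bayes moment estimator against 5000 simulated
variances.  These sizes were chosen so the full suite runs in well under
a minute of compute per heavy test while leaving Monte-Carlo error small
relative to every asserted tolerance.

## Known limitations

* No covariates in the class-membership or trajectory submodels (by
  design, matching the descriptive aim); no splines; no joint survival
  models; no bootstrap likelihood-ratio test for class number.
* GMM fits use numerical gradients; at large n the GBTM path is much
  faster and is the default throughout.
* Posterior-band curves use a responsibility-weighted OLS approximation
  rather than the full information matrix.
* The g-computation risk-ratio route bootstrap is percentile-only.
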