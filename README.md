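# deptraj

Latent-class trajectory modelling of repeated depressive-symptom scores
across adolescence, with downstream association of the assigned
trajectory classes with clinical outcomes and high-dimensional blood
biomarkers.  The package is aimed at epidemiologists and biostatisticians
working with birth-cohort data of the UK type: a 13-item mood questionnaire
(total score 0–26) measured on ten occasions between ages 10 and 25,
subject-level covariates, binary/continuous health outcomes, and
proteomic / metabolomic / clinical-chemistry panels.  Because such cohort
data are managed-access, the package ships a first-class synthetic-cohort
generator that emulates the full study design, so every stage of the
analysis is runnable and testable out of the box.

## The models

**Trajectory mixture.**  For subject *i* with score vector *y<sub>i</sub>*
observed at ages *t<sub>i</sub>* and fractional-polynomial design
*X<sub>i</sub>*, the marginal likelihood is a finite Gaussian mixture

&nbsp;&nbsp;ℓ = Σ<sub>i</sub> log Σ<sub>g</sub> π<sub>g</sub>
𝒩(y<sub>i</sub>; X<sub>i</sub>β<sub>g</sub>, V<sub>ig</sub>),
&nbsp;&nbsp;V<sub>ig</sub> = ω<sub>g</sub>²τ²𝟙𝟙ᵀ + σ²I,

covering group-based trajectory models (GBTM, τ = 0) and growth mixture
models with a common (ω<sub>g</sub> ≡ 1) or class-proportional random
intercept.  Fractional-polynomial bases use powers from
{−2, −1, −0.5, 0, 0.5, 1, 2, 3}, with 0 meaning log *x* and repeated
powers contributing *x*<sup>p</sup> log *x*.  Estimation is maximum
likelihood with a multistart schedule (50 short runs, best start run to
convergence); posteriors p<sub>ig</sub> = π<sub>g</sub>f<sub>g</sub>(y<sub>i</sub>)/Σ<sub>h</sub>π<sub>h</sub>f<sub>h</sub>(y<sub>i</sub>)
also classify subjects with as few as one scored occasion.

**Model selection.**  A staged procedure: class-number sweep by
BIC/ICL/relative entropy with convergence and a ≥ 5% smallest-class gate;
structure comparison under adequacy gates (average posterior probability
≥ 0.7, odds of correct classification ≥ 5 per class); fractional-polynomial
refinement by BIC.

**Downstream associations.**  Binary outcomes: modified Poisson
regression (log-link Poisson, robust sandwich variance) giving adjusted
risk ratios versus the largest ("low-stable") class; continuous outcomes:
OLS.  Biomarkers: per-analyte linear models over a shared design with
empirical-Bayes variance moderation (residual variances shrunk toward a
moment-matched scaled-inverse-χ² prior (d₀, s₀²); moderated *t* on
d₀ + d<sub>g</sub> df) and planned contrasts against the reference class,
with Benjamini–Hochberg FDR flags at q = 0.1.  Panel hygiene follows
delivery conventions: proteins with ≥ 50% of values below the limit of
detection are excluded, and lipoprotein-subclass features are dropped
from the metabolomic set.

## Worked example

```python
import numpy as np
from deptraj import GeneratorConfig, TrajectoryModel, generate_cohort, generate_outcomes
from deptraj.simulate import DEFAULT_DEPRESSION_OUTCOME
from deptraj.smfq import score_table, fitting_sample
from deptraj.associations import fit_binary_outcome

cohort = generate_cohort(GeneratorConfig(n_subjects=2000, seed=1))
scores = fitting_sample(score_table(cohort.occasions))
model = TrajectoryModel(n_classes=4, random_state=1).fit(scores)
print("estimated class shares (%):", np.round(model.mixing_ * 100, 1))

outcomes = generate_outcomes(cohort, DEFAULT_DEPRESSION_OUTCOME, seed=2)
df = cohort.covariates.rename(columns={"true_class": "trajectory_class"}).merge(
    outcomes, on="subject_id")
for r in fit_binary_outcome(df, "icd10_depressive_episode", reference=1):
    print(f"{r.contrast_class}: RR {r.effect:.2f} "
          f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")
```

prints

```
estimated class shares (%): [70.3 13.1 10.3  6.3]
trajectory_class[2]: RR 2.90 (95% CI 1.69-4.98)
trajectory_class[3]: RR 9.96 (95% CI 6.45-15.39)
trajectory_class[4]: RR 5.38 (95% CI 3.36-8.62)
```

The four estimated shares recover the generator's planted mixing
proportions (69.7/13.3/10.0/7.0%, descending), and the risk ratios are
single-replicate estimates of the planted class effects (3.65/13.11/6.25)
on a cohort where the outcome has ~2% baseline risk — individual
replicates are noisy at ~60 reference-class events; averaging over
replicates recovers the planted values (see below).

A complete pipeline (simulate → score → fit → select → assign →
associate → ebayes) is available from the shell:

```bash
deptraj --config examples/config.yaml all
```

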