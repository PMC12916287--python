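# Example pipeline configuration.
# Run:  deptraj --config examples/config.yaml all
outdir: scratch/pipeline_demo
seed: 1

generator:
  n_subjects: 1000          # subjects in the synthetic cohort
  # occasion_ages, class_proportions, trajectory shapes, missingness and
  # covariate distributions default to the emulated study design.

outcomes:
  - kind: binary
    outcome_name: icd10_depressive_episode
    baseline_risk: 0.02
    class_risk_ratios: {"2": 3.65, "3": 13.11, "4": 6.25}

model_grid:
  n_classes: [1, 2, 3, 4, 5, 6]
  structures: [none]        # none = GBTM; also: common_intercept,
                            # class_proportional_intercept
  fp_powers: [[1.0, 2.0]]
  multistart: {n_starts: 50, burn_iters: 10, final_iters: 500}

gates:
  min_class_share: 0.05
  min_app: 0.7
  min_occ: 5.0

association:
  model: adjusted           # sex + maternal education + social class + BMI(10)

fdr_q: 0.1
min_measurements: 3
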