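# End-to-end demo: simulate a three-cohort trio sized like the study
# cohorts (69 / 77 / 134 samples) with one planted prognostic gene
# (per-SD log-hazard ln(2.5) ~ 0.9163), screen every gene in every cohort,
# intersect, and refine the ELN grouping with each intersection gene.
seed: 7
endpoint: OS
horizon: 36
gates:
  auc: 0.5
  sensitivity: 0.5
  specificity: 0.5
  alpha: 0.05
  gate_mode: strict
confounders: [age, sex, wbc, transplant, eln]
simulate:
  n_genes: 40
  planted:
    0: 0.9162907318741551
  censoring: 0.35
  cohorts:
    - {name: trioA, n_samples: 69}
    - {name: trioB, n_samples: 77}
    - {name: trioC, n_samples: 134}
refinement:
  base_column: eln
  mapping: default
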