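# End-to-end demo at desk scale: simulate a 12-item cohort with a planted
# severity gradient (two genetic factors, rg 0.6) plus an ascertained
# disorder trait, then binarize -> GWAS -> multivariate LDSC -> GLS + SEM.
# Runs in a few minutes on one CPU:  gtaccc pipeline --config configs/demo.yaml --out demo_run
seed: 1
n_blocks: 120
ld_window: 20
matrix: R
quadratic: false
factors: [1, 2]
simulate:
  n_ind: 20000
  n_var: 3600
  ld_blocks: 180
  ld_r: [0.2, 0.95]
  maf_range: [0.05, 0.5]
  n_items: 12
  h2_low: 0.75
  h2_high: 0.75
  rg_fact: 0.6
  item_prev_range: [0.72, 0.28]
  weight_steepness: 12.0
  disorder:
    b_low: 0.0
    b_high: 0.9
    K: 0.15
    P_target: null
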