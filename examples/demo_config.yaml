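# Bundled demo scenario: synthetic 500-gene x 200-sample matrix with five
# planted inversely-correlated ARE-positive targets of the regulator.
# Identical to are_regnet.pipeline.demo_config(seed=1).
seed: 1
regulators: [ZFP36L1]
n_perm: 10000
q_threshold: 0.01
min_are_copies: 2
require_negative_lr: true
annotation_terms: [apoptosis]
simulate:
  n_genes: 500
  n_samples: 200
  n_linear_targets: 5
  n_nonlinear_targets: 0
  noise_sd: 0.5
  linear_slope: -2.0
  utr_length: 300
  utr_target_copies: 2
  n_background_with_are: 10
  n_background_annotated: 50
  validation:
    n_true_in_set: 5
    n_decoys: 20
gsea:
  weight: 1.0
  n_perm: 200
outdir: are_regnet_out
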