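# Demonstration pipeline configuration (fully synthetic, deterministic).
# Run with:  longtraj run-all --config examples/demo_config.yaml --outdir demo_out
seed: 42
outdir: demo_out
cohort:
  n_birth_cohort: 6000
  n_snps: 200
  sample_sizes: [381, 392, 333]
  base_surv_mid: 0.85
  base_surv_late: 0.2
  sex_effect: -0.4
gwas:
  case_groups: [G3]
  control_groups: [G1, G2]
  maf: 0.01
trajectory:
  alpha: 0.01
  combine: fisher
structure:
  n_snps: 600
  fst: 0.08
  pop_sizes: [120, 120, 120]
  n_supplementary: 40
  supplementary_pop: 2
  n_pcs: 8
ancestry:
  group_means:
    centenarians: [0.038, 0.481, 0.481]
    controls: [0.023, 0.4885, 0.4885]
  concentration: 50
  group_sizes: [333, 773]
  component: 1
  test: welch
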