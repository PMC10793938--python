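# Default study conditions: a biobank-scale continuous-exposure GWAS
# (~440k samples, ~100 independent instruments explaining ~18% of variance)
# against a registry case-control outcome GWAS (4,172 cases / 303,280
# controls), true causal effect 0.398 log-odds per SD (OR 1.489).
# Use with: summr simulate --config examples/paper_like.yaml --out scratch/sim
seed: 1
k_snps: 100
maf_range: [0.05, 0.5]
exposure_h2: 0.18
n_exposure: 440000
n_outcome: 307452
case_fraction: 0.0136
theta: 0.39810475
pleiotropy:
  mode: none
  alpha_mean: 0.0
  alpha_sd: 0.0
  prop_invalid: 0.0
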