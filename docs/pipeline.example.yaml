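# Example full-pipeline configuration for `ssrdem run --config ...`.
# Omit `genotypes` to analyze the builtin synthetic worldwide panel.
genotypes: panel.csv
dialect: csv
out_dir: ssrdem_out
k_min: 2
k_max: 6
n_runs: 3
mcmc: [300, 1500, 10]      # burn-in, iterations, thinning
n_perm: 200
n_boot: 200
bottleneck_models: [iam, smm, tpm]
tpm_single: 0.95
tpm_var: 12.0
heq_iters: 1000
abc_enabled: false          # enable only with exactly 5 consensus clusters
seeds:                      # every stochastic stage needs an explicit seed
  diversity: 1
  differentiation: 2
  admixture: 3
  bottleneck: 4
  abc: 5
  core: 6
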