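# Example run configuration for the svybias CLI.
# Exactly one of `input:` (child_csv/cluster_csv paths) or `simulate:`
# must supply the data; this one simulates.
simulate:
  n_clusters_total: 500
  children_per_cluster: 120
  urban_fraction: 0.15
  cluster_effect_sd: 0.5
  sampled_clusters: 100
  children_sampled_per_cluster:
    urban: 12
    rural: 22
  informativeness: 0.0
  seed: 1

model:
  outcome: y
  covariates:
    sex: [male, female]          # first level is the reference
    residence: [urban, rural]
  weighting: pseudo_likelihood   # unweighted | pseudo_likelihood | eq7_literal

experiment:
  # fractions default to [1.0, 0.75, 0.50, 0.25] when omitted
  reference_rate: 0.09
  reference_unit: proportion     # or per_1000
  replicates: 1
  seed: 1
  include_population_weighted: true

out_dir: results
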