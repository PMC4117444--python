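# Packaged default experiment: founder vs outbred cohorts, one LoF variant
# lowering a biomarker that drives disease risk. All thresholds shown are
# the pipeline defaults; edit and pass to `founderscan run --config`.
sim:
  ancestral_size: 500000       # effective size of the outbred comparison population
  bottleneck_size: 1000        # founding bottleneck, diploids
  present_size: 500000         # founder population after exponential regrowth
  generations_post_bottleneck: 100
  n_sites_per_class: 8000
  sample_sizes:
    founder: 3000
    outbred: 3000
  substructure_F: 0.0
  class_specs:
    - label: synonymous
      s: 0.0
      q0: [1.0e-6, 0.05]
      q0_shape: growth         # density ~ q^-1.5: expansion-shaped spectrum
    - label: lof
      s: 0.01
      h: 0.5
      q0: [1.0e-6, 0.01]
      q0_shape: growth
effects: []                    # empty -> pipeline picks a ~2% LoF variant,
                               # beta = -0.6 SD/allele, 0.3 log-hazard/SD
screen_p: 2.0e-4
alpha: 0.05
freq_window: [0.005, 0.05]
min_fold: 2.0
concordance_threshold: 1.0e-5
min_expected_hom: 3.0
deficit_p: 0.05
discovery_fraction: 0.67
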