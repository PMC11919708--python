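# Study configuration shared by the numbered analysis drivers.
#
# The scaled-down study mirrors the full survey design: two training years
# of the May-August season (8 monthly models per engine) plus a held-back
# projection year evaluated with the two forward-projection protocols.

seed: 7

world:
  shape: [64, 64]
  cell_size: 500.0        # metres
  n_sightings: 150        # presences sampled per month
  tours_range: [30, 60]   # boat tours per month

months:
  training:
    - "2018-05"
    - "2018-06"
    - "2018-07"
    - "2018-08"
    - "2019-05"
    - "2019-06"
    - "2019-07"
    - "2019-08"
  projection:
    - "2020-05"
    - "2020-06"
    - "2020-07"
    - "2020-08"

engines:
  maxent:
    beta: 1.0
    knots_per_covariate: 8
    max_iterations: 500
  network:
    l1_strength: 0.005
    learning_rate: 0.2
    max_iterations: 500
    patience: 5

evaluation:
  cv_folds: 10
  importance_repeats: 10
  min_support: 5

paths:
  data: results/data
  study: results/study
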