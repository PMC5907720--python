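# Reduced-scale penetrance-architecture benchmark (see docs/methods.md).
experiment: gametes
methods: [mdr, rf, gbm, "turf:multisurf_star"]
percentages: [3, 5, 10]
replicates: 5
seed: 1
h2_levels: [0.1, 0.2, 0.4]
architectures: [hard, easy]
n_candidates: 2000
selector_overrides:
  rf_n_trees: 500
  gbm_n_trees: 1000
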