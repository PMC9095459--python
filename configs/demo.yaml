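# Desk-scale end-to-end demo on the mini-genome (4 x 25 Mb -> 20 bins).
# Runs in well under a minute; raise n_cases/n_controls, rounds and rf_trees
# for a study-scale run.
seed: 17
simulate:
  preset: strong
  n_cases: 60
  n_controls: 60
  n_effect_bins: 3
maf_threshold: 0.05
counting_mode: presence
categories: [nonsynonymous, intronic]
evaluate:
  tasks: [case_control, multilabel]
  rounds: 3
  rf_trees: 60
  mlp:
    hidden_layer_sizes: [16]
    max_iter: 300
hotspots:
  threshold: 0.01
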