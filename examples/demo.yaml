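# Demo pipeline run on synthetic inputs.
# Usage: thermalgarden all --config examples/demo.yaml
seed: 1
outdir: thermalgarden_out
simulate:
  # one injected marine heatwave in the lethal year's summer
  injected_events:
    - ["2017-06-20", 7, 2.5]
trim_before_day: 10
n_permutations: 1000
n_randomizations: 10000
max_k: 3
max_pcs: 100
t_threshold: 23.0
min_mhw_duration: 5
baseline: [2004, 2016]
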