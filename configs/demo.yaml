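# Demo pipeline configuration: a small synthetic season end to end.
out_dir: results/demo
seed: 7
n_events: 40
site: demo_beach
k_folds: 10
n_reps: 100
collinearity_threshold: 0.8
exclude: [uv254, rain_48h]
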