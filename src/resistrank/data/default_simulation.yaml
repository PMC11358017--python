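# Default multi-cohort simulation: 4 heterogeneous cohorts over a
# 10,000-gene universe of which 1,321 genes are flagged metabolic
# (the shape of a four-dataset responder/non-responder screen).
n_genes: 10000
n_studies: 4
n_responders: 10
n_nonresponders: 10
baseline_mean: 6.0
baseline_sd: 2.0
batch_sd: 0.5
noise_sd: 1.0
dropout: 0.0
dropout_floor: 0.0
metabolic_fraction: 0.1321
spikes: {}
seed: 0
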