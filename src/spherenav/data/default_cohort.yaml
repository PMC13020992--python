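# Default cohort parameters for the synthetic triangle-completion data.
# Noise scales are calibrated so that the per-participant R^2 against the
# true (responder-geometry) turn predictor lands near 0.67 and the
# distance R^2 near 0.36 under the default design.
n_participants: 20
responder_geometry: planar
slope_mean: 1.0
slope_sd: 0.15
intercept_mean: 0.0
intercept_sd: 10.0
turn_noise_sd: 14.0
distance_noise_sd: 31.0
repetitions: 4
seed: 0
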