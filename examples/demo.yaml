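# Small demonstration cohort: completes in about a minute on one CPU.
out_dir: demo_out
seed: 1
n_subjects: 8
n_networks: 4
grid_shape: [8, 8, 8]
n_volumes: 105
tr: 2.0
noise_sd: 0.5
effect_networks: [0, 1]
delta_mean_pct: 10.0
delta_sd_pct: 3.0
clinical_effect: -0.8
clinical_noise_sd: 2.0
fd_thresh: 0.5
head_radius: 50.0
drop_initial: 5
lam_scale: 0.5
max_iter: 250
tol: 1.0e-06
percentile: 95.0
min_active_frac: 0.01
n_clusters: 4
k_range: [2, 8]
n_replicates: 20
n_resamples: 30
subsample_frac: 0.8
run_consensus: false
z_thresh: 1.0
n_perm: 200
n_boot: 200
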