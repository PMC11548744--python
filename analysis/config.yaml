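# Shared configuration of the synthetic end-to-end analysis.
# Scale: 3 organs x 12 genes (36 network nodes) keeps the full fit in
# seconds while exercising every stage at the study's factorial layout
# (2 strains x 5 ages x 3 animals, Ct-scale noise, light missingness).
out_dir: results/pipeline
ct_csv: null
meta_csv: null
seed: 20260101
n_organs: 3
n_genes: 12
replicates_per_cell: 3
ages_weeks: [8.0, 10.0, 12.0, 16.0, 24.0]
density: 0.05
coeff_scale: 0.2
stability_bound: -0.05
noise_sd: 0.25
missing_rate: 0.02
chip_replicate_fraction: 0.1
min_present: 0.6
replicate_band: [0.85, 1.15]
hmf_M: 8
hmf_N: 3
n_grid: 257
l1_ratio: 0.5
penalty_grid: []
sim_span: [8.0, 24.0]
sim_n_out: 161
sd_factor: 2.0
max_fraction: 0.75
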