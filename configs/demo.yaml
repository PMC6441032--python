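# Desk-scale demo experiment: a 15 x 20 grid world with 20 virtual species,
# a 2 GCM x 2 RCP x 1 period scenario design, the four SDM algorithm families
# with four cross-validation repetitions, and the three TSS retention
# thresholds.  Runs end to end in a few minutes on one CPU.
n_rows: 15
n_cols: 20
cell_size_km: 100.0
corr_length: 3.0
gcm_ids: [CESM1-BGC, MIROC5]
rcp_ids: [RCP2.6, RCP8.5]
combos: null            # null -> full factorial of the lists above
periods: ["2041-2060"]
n_species: 20
prevalence_range: [0.08, 0.3]
taxon_mix: {amphibian: 0.12, bird: 0.63, mammal: 0.25}
buffer_km_by_taxon: {amphibian: 2000.0, mammal: 3000.0, bird: 4000.0}
n_regions: 6
algorithms: [GLM, GAM, BRT, RF]
n_repetitions: 4
split_fraction: 0.7
n_absences: null        # null -> min(10 * presences, all buffer cells)
tss_thresholds: [0.4, 0.6, 0.7]
delta_beta_semantics: whittaker
range_size_bins: 3
partition_scheme: nested
seed: 1
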