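# The study-scale scenario design: five GCMs x four RCPs restricted to the
# default 14-combo unbalanced subset, two future periods, on a larger world
# with more species.  This is the configuration whose design arithmetic gives
# 4 x 4 x 14 x 2 = 448 future projections per species.  Expect a run of tens
# of minutes; the demo config covers routine use.
n_rows: 30
n_cols: 40
cell_size_km: 100.0
corr_length: 3.0
gcm_ids: [CESM1-BGC, CMCC-CMS, CM5A-LR, MIROC5, ESM-MR]
rcp_ids: [RCP2.6, RCP4.5, RCP6.0, RCP8.5]
combos:
  - [CESM1-BGC, RCP4.5]
  - [CESM1-BGC, RCP8.5]
  - [CMCC-CMS, RCP4.5]
  - [CMCC-CMS, RCP8.5]
  - [CM5A-LR, RCP4.5]
  - [CM5A-LR, RCP8.5]
  - [MIROC5, RCP4.5]
  - [MIROC5, RCP8.5]
  - [ESM-MR, RCP4.5]
  - [ESM-MR, RCP8.5]
  - [CESM1-BGC, RCP2.6]
  - [CM5A-LR, RCP2.6]
  - [MIROC5, RCP6.0]
  - [ESM-MR, RCP6.0]
periods: ["2041-2060", "2061-2080"]
n_species: 60
prevalence_range: [0.03, 0.2]
taxon_mix: {amphibian: 0.12, bird: 0.63, mammal: 0.25}
buffer_km_by_taxon: {amphibian: 2000.0, mammal: 3000.0, bird: 4000.0}
n_regions: 12
algorithms: [GLM, GAM, BRT, RF]
n_repetitions: 4
split_fraction: 0.7
n_absences: null
tss_thresholds: [0.4, 0.6, 0.7]
delta_beta_semantics: whittaker
range_size_bins: 4
partition_scheme: nested
seed: 1
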