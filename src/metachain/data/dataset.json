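{
  "n_autopsies": 3827,
  "n_primaries": 3827,
  "n_metastases": 9484,
  "n_primary_tumor_types": 41,
  "n_metastatic_sites_overall": 30,
  "n_lung_target_sites": 27,
  "lung_site_id": 23,
  "reference_site_id": 24
}
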