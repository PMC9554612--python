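{
  "n_initial_qtls": 459,
  "n_studies": 48,
  "n_projected": 304,
  "n_not_projected": 155,
  "n_regions": 65,
  "n_mqtls": 57,
  "n_hotspots": 7,
  "n_member_qtls": 233,
  "n_singletons": 45,
  "n_non_supporting": 26,
  "n_gwas_verified_mqtls": 19,
  "n_gwas_verified_hotspots": 2,
  "ci_fold_reduction": 2.71
}
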