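{
  "cohort_families.tsv": "54190f891ce0c16ffa412065270bd4c5233c47a528db9965e520464320aaaa91",
  "comparison_counts.tsv": "c41bab5c47d37bf35654ba6600e6e5bdea37629936025743439e87d99840b236",
  "reported_variants.tsv": "72477604f3e8a79d4c285dabb8a6de50dbaa90fc949f5b0ce5c02b813af5c1b3",
  "gms_reported_variants.tsv": "874d139bf04e534d0f5b8b3d9abf10c3dab2a0184ee806be6a64428ab5e6e1c3"
}
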