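af_max_dominant: 0.001
af_max_recessive: 0.01
allele_balance_min: null
cadd_min: null
clinvar_override: false
clinvar_override_af_ceiling: 0.05
cnv_min_size_bp: 10000
coding_window_bp: 8
cohort_af_max: null
exomiser_rank_max: 3
exomiser_score_min: 0.95
gq_all_members: false
gq_min: 30
plof_terms:
- frameshift
- splice_acceptor
- splice_donor
- start_lost
- stop_gained
- stop_lost
remove_benign: false
require_pass: true
spliceai_min: null
strategy: gms
transcript_set: null
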