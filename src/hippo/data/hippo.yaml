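af_max_dominant: 0.001
af_max_recessive: 0.05
allele_balance_min: 0.2
cadd_min: 15.0
clinvar_override: true
clinvar_override_af_ceiling: 0.05
cnv_min_size_bp: 10000
coding_window_bp: 20
cohort_af_max: 0.01
exomiser_rank_max: 3
exomiser_score_min: 0.95
gq_all_members: false
gq_min: 40
plof_terms:
- frameshift
- splice_acceptor
- splice_donor
- start_lost
- stop_gained
- stop_lost
remove_benign: true
require_pass: false
spliceai_min: 0.2
strategy: hippo
transcript_set: null
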