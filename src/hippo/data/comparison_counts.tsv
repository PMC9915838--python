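# Per-family variant counts from the published strategy comparison.
# hippo_n: variants passing the panel-agnostic HiPPo filter on the research exome.
# gencc_n: the subset of hippo_n in GenCC strong/definitive disease genes.
# gms_n: short variants passing the GMS panel-based filtering (Tier 1 + Tier 2 +
#        gene-agnostic channel; CNVs excluded). Empty = no GMS report returned.
# comparable: 1 when both arms analysed the same trio structure. FAM_4's exome
#   arm lacked the maternal sample (trio = father + twins) while the GMS genome
#   arm sequenced two full trios, so its counts are not paired; FAM_7's GMS
#   report was never returned.
family	proband	hippo_n	gencc_n	gms_n	comparable	gms_report_returned
FAM_1	1	8	3	9	1	1
FAM_2	4	4	4	5	1	1
FAM_3	7	4	2	7	1	1
FAM_4	10;13	68	23	14	0	1
FAM_5	14	8	1	5	1	1
FAM_6	17	2	1	6	1	1
FAM_7	20	62	21		0	0
FAM_8	23	10	1	7	1	1
FAM_9	26	5	3	24	1	1
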