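# Study cohort family structures: 9 families (8 trios and one quad), anonymised ids.
# The quad (FAM_4) has two affected monozygotic twin probands sharing both parents
# and is analysed as two trios with the parents duplicated.
# FAM_7's father (21) was consented but never sequenced (duo analysis).
family	individual	father	mother	sex	affected
FAM_1	1	2	3	male	1
FAM_1	2	0	0	male	0
FAM_1	3	0	0	female	0
FAM_2	4	5	6	male	1
FAM_2	5	0	0	male	0
FAM_2	6	0	0	female	0
FAM_3	7	8	9	female	1
FAM_3	8	0	0	male	0
FAM_3	9	0	0	female	0
FAM_4	10	11	12	female	1
FAM_4	13	11	12	female	1
FAM_4	11	0	0	male	0
FAM_4	12	0	0	female	0
FAM_5	14	15	16	female	1
FAM_5	15	0	0	male	0
FAM_5	16	0	0	female	0
FAM_6	17	18	19	female	1
FAM_6	18	0	0	male	0
FAM_6	19	0	0	female	0
FAM_7	20	21	22	female	1
FAM_7	21	0	0	male	0
FAM_7	22	0	0	female	0
FAM_8	23	24	25	male	1
FAM_8	24	0	0	male	0
FAM_8	25	0	0	female	0
FAM_9	26	28	27	female	1
FAM_9	27	0	0	female	0
FAM_9	28	0	0	male	0
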