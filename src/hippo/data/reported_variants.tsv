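# The 17 variants reported by the research exome study after HiPPo filtering
# and application of the reporting exclusion criteria, with their printed
# annotations. gnomad_af is the maximum population allele frequency; p_ac /
# s2_ac / s3_ac are proband and other-sample alt allele counts (sample2 and
# sample3 are the parents, except FAM_4 where sample3 is the identical twin
# and FAM_7 where only the mother was sequenced). mode records the search the
# variant belongs to: dominant for de novo / single-het findings, recessive
# for the in-trans compound-heterozygous pairs. diagnostic = clinically
# accepted as a (partial) diagnosis. Empty cells are absent annotations.
chrom	pos	ref	alt	gene	consequence	gnomad_af	cadd	revel	hgvsc	hgvsp	clinvar	acmg	family	proband	p_ac	sample2	s2_ac	sample3	s3_ac	returned_by_gms	mode	diagnostic
13	30462666	CT	C	HMGB1	frameshift	0	38		ENST00000341423.9:c.342del	p.Gly115GlufsTer37		VUS	FAM_1	1	1	2	0	3	0	1	dominant	0
7	1480876	G	C	INTS1	missense	5.56e-4	23.5	0.243	ENST00000404767.7:c.3908C>G	p.Thr1303Ser		VUS	FAM_2	4	1	5	1	6	0	0	recessive	0
7	1497193	C	G	INTS1	missense	7.76e-5	24	0.315	ENST00000404767.7:c.1547G>C	p.Cys516Ser		VUS	FAM_2	4	1	5	0	6	1	0	recessive	0
2	28776944	C	G	PPP1CB	missense	0	26.7	0.438	ENST00000395366.2:c.146C>G	p.Pro49Arg	P	P	FAM_3	7	1	8	0	9	0	1	dominant	1
1	31731030	G	A	ADGRB2	stop_gained	0	38		ENST00000373655.6:c.4150C>T	p.Arg1384Ter		VUS	FAM_4	13	1	11	0	13	1	0	dominant	0
1	31731030	G	A	ADGRB2	stop_gained	0	38		ENST00000373655.6:c.4150C>T	p.Arg1384Ter		VUS	FAM_4	10	1	11	0	13	1	0	dominant	0
13	114325034	C	T	CHAMP1	stop_gained	0	35		ENST00000643483.1:c.1192C>T	p.Arg398Ter	P	P	FAM_6	17	1	18	0	19	0	1	dominant	1
11	17413408	G	A	ABCC8	stop_gained	0	43		ENST00000302539.9:c.2464C>T	p.Gln822Ter		LP	FAM_5	14	1	15	0	19	1	0	dominant	1
11	124959205	C	T	CCDC15	stop_gained	9.27e-6	32		ENST00000344762.5:c.268C>T	p.Arg90Ter		VUS	FAM_7	20	1	22	0			0	recessive	0
11	124975120	C	T	CCDC15	missense	2.02e-4	24	0.158	ENST00000344762.5:c.541C>T	p.Arg181Cys		VUS	FAM_7	20	1	22	1			0	recessive	0
19	10908113	A	G	CARM1	missense	0	23.7	0.255	ENST00000327064.8:c.421A>G	p.Thr141Ala		VUS	FAM_7	20	1	22	0			0	dominant	0
16	71951734	T	G	PKD1L3	missense	5.09e-4	23.1		ENST00000620267.1:c.3020A>C	p.Glu1007Ala		VUS	FAM_8	23	1	24	1	25	0	0	recessive	0
16	71973386	C	T	PKD1L3	missense	1.02e-4	22		ENST00000620267.1:c.1891G>A	p.Ala631Thr		VUS	FAM_8	23	1	24	0	25	1	0	recessive	0
9	77020700	A	G	FOXB2	missense	0	25.3	0.534	ENST00000376708.1:c.1046A>G	p.Lys349Arg		VUS	FAM_8	23	1	24	0	25	0	0	dominant	0
19	23361341	G	C	ZNF91	stop_gained	0	32		ENST00000300619.11:c.1638C>G	p.Tyr546Ter		VUS	FAM_9	26	1	27	0	28	0	0	dominant	0
1	243341070	TG	T	SDCCAG8	frameshift	0	26		ENST00000366541.7:c.1255del	p.Glu419ArgfsTer43		P	FAM_9	26	1	27	1	28	0	1	recessive	0
1	243378799	A	G	SDCCAG8	missense	9.55e-5	22.2	0.195	ENST00000366541.7:c.1552A>G	p.Arg518Gly	VUS	VUS	FAM_9	26	1	27	0	28	1	1	recessive	0
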