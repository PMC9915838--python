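# The 5 variants included on the final clinical genome reports issued by the
# NHS laboratory (4 patients): two diagnoses, one VUS in a novel gene, and a
# compound-heterozygous pathogenic + VUS pair. diagnostic = accepted as
# explaining (or partially explaining) the phenotype.
# Coordinates harmonised to the reported-variants table where the source
# printed inconsistent positions for the SDCCAG8 missense.
family	chrom	pos	ref	alt	gene	classification	diagnostic
FAM_1	13	30462666	CT	C	HMGB1	VUS	0
FAM_3	2	28776944	C	G	PPP1CB	P	1
FAM_6	13	114325034	C	T	CHAMP1	P	1
FAM_9	1	243341070	TG	T	SDCCAG8	P	0
FAM_9	1	243378799	A	G	SDCCAG8	VUS	0
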