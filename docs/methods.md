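# Methods

## The problem and the two strategies

A sequenced trio yields on the order of 10⁴ rare coding variants; a
laboratory can review tens.  Two reduction strategies are implemented and
compared on equal footing:

**HiPPo (panel-agnostic).**  A variant is retained iff *all* applicable
rules pass, or the ClinVar override fires:

| rule | dominant search | recessive search |
|---|---|---|
| max population AF (gnomAD exomes/genomes, TOPMed, ExAC, 1000G) | < 0.001 | < 0.05 |
| cohort AF (joint-call frequency) | < 0.01 | < 0.01 |
| consequence | coding ±20 bp, excluding synonymous, on any transcript | same |
| SpliceAI (splicing variants only) | > 0.2 | > 0.2 |
| CADD (when present) | > 15 | > 15 |
| ClinVar | not benign / likely benign | same |
| proband allele balance (het calls) | > 0.2 | > 0.2 |
| proband genotype quality | > 40 | > 40 |
| FILTER | any | any |

Override: a ClinVar pathogenic / likely-pathogenic assertion retains the
variant regardless of scores, quality or presence in unaffected parents,
subject to a population-AF safety ceiling of 0.05 (guarding against
miscurated common alleles; the ceiling is a package choice — the source
protocol states the override without one).

**GMS tiering (panel-based).**  Pre-filter: max AF < 0.001 (dominant) /
< 0.01 (recessive), coding ±8 bp non-synonymous, GQ > 30, FILTER PASS.
Tier 1 = predicted LoF or de novo in a green panel gene; Tier 2 = other
qualifying coding variants in a green panel gene; gene-agnostic channel
(bypasses GQ/PASS, "not filtered on quality") = de novo coding variants and
Exomiser rank ≤ 3 with score ≥ 0.95; Tier A = CNV > 10 kb overlapping a
ClinGen pathogenic region or green panel gene by ≥ 1 base.  Synonymous
variants are never tiered, even with high splice scores.  Everything else
is UNTIERED and not reviewed.

All printed thresholds are strict inequalities except the Exomiser score
(≥ 0.95).  Boundary values therefore fail: allele balance exactly 0.2,
GQ exactly 40 (HiPPo) or 30 (GMS), CADD exactly 15, a CNV of exactly
10 000 bp.

## Inheritance model

Labels are assigned per (variant, proband) with precedence
de novo → hemizygous → homozygous-recessive → inherited het → uninformative:

* **de novo** requires both parents *present with genotype data* and
  hom-ref; a missing parental genotype can never yield a de novo call
  (conservative default for joint-called trios).
* **hemizygous**: X non-PAR (GRCh38 PAR1/PAR2 by default, configurable),
  male proband carrying alt, mother het, father a non-carrier.  Hemizygous
  variants enter the recessive search; this treatment is a package decision
  (the source protocol leaves it unstated) and is flagged via the label.
* **compound heterozygotes**: two proband-het variants in one gene pair iff
  transmitted by different parents (in trans); an unphased de novo het may
  pair with either inherited het, since cis cannot be proven.  Two variants
  from the same parent never pair.  A het whose both parents carry the
  allele is uninformative (transmission side unknowable without read-backed
  phasing, which is out of scope).
* In the pipeline, an inherited het that fails the dominant AF ceiling is
  re-screened under the recessive ceilings iff it has a trans partner, and
  a pair only counts when both members survive.

## Absent annotations

Absence is represented as `None`, never 0, and the two are handled
differently by design: an absent allele frequency means "never observed"
and passes frequency rules (AF treated as 0 — a novel variant); an absent
*score* abstains from its rule with a trail note (`note:cadd_absent`,
`note:spliceai_absent`) rather than failing, because HiPPo is a
sensitivity-first research filter and absence of a prediction is not
evidence of benignity.  Canonical splice-site disruptions with no SpliceAI
score are retained as predicted LoF.  Absent Exomiser annotations make a
variant ineligible for the gene-agnostic channel (the channel consumes the
ranking, it does not recompute it).

## Reporting exclusions

Six ordered criteria map each retained candidate to reportable /
excluded(criterion): (1) lone het in a recessive gene without a second hit;
(2) phenotype mismatch in a known disease gene unless ClinVar P/LP;
(3) inadequate tissue (GTEx) or exon (pext) expression in a known gene;
(4) novel gene with inadequate expression or explicit pathway exclusion;
(5) predicted LoF curated as not-LoF; (6) read-level artefact.  The
human-judgement inputs arrive as evidence flags; `unknown` makes a rule
abstain (listed in the decision) and can never exclude.  The lowest firing
criterion is recorded.  Expression adequacy defaults, where a caller
supplies raw values, are TPM ≥ 1 and pext ≥ 0.1 — package choices, as the
protocol names the resources but no cut-offs.

## Comparison statistics

Per family, each strategy's *assessed* count is the number of variants left
for manual review (CNVs are excluded from both arms — they are not
assessed in exome data).  Families lacking results in either arm, or whose
trio structures differ between arms, are dropped from all paired
quantities.  Efficiency = 100 × hits / assessed, where hits are diagnostic
(clinically accepted P/LP explaining the phenotype — a consumed flag,
never inferred) or reportable variants.  The GenCC-restricted rates divide
the same numerators by the GenCC-restricted assessed denominator,
mirroring the headline arithmetic of the comparison.  Overlap is
(chrom, pos, ref, alt) identity between the two reported sets.

The paired Wilcoxon signed-rank test drops zero differences, mid-ranks
ties, and reports V = sum of positive-difference ranks.  The default
method is the normal approximation with continuity correction and
tie-variance correction — the convention that reproduces the published
p-values (0.022 for GenCC-restricted HiPPo vs GMS; 0.35 for all-gene HiPPo
vs GMS) on the packaged per-family counts.  An exact method enumerating
all 2ⁿ sign assignments is also provided; on the n = 7 GenCC pairs it
gives 0.016, a documented divergence of convention, not a bug.  Fewer than
3 non-zero differences make the test undefined (error); all-zero
differences return p = 1 with a warning.

## Packaged study tables

`hippo/data/` ships four checksummed TSVs transcribed from the comparison
study: family structures, per-family assessed counts (with comparability
flags), the 17 exome-reported variants with printed annotations, and the 5
genome-reported variants.  Two transcription notes: the per-family count
column is used as-is (its column sum, 171, differs from a prose total of
174 in the source; the per-family values are authoritative for all derived
arithmetic), and one reported variant's coordinates were printed
inconsistently between tables — the variant-detail table's coordinate is
used in both fixtures so that site-identity overlap is computable.

## The synthetic cohort

The generator emulates the *annotation structure* of a joint-called,
VEP-annotated multi-sample trio VCF: per-transcript consequences with exon
distances, five population AF sources, cohort AF, CADD/REVEL/SpliceAI,
ClinVar assertions, FILTER status and per-sample GT:AD:GQ.  Coordinates
are synthetic (one contig per gene, three 200 bp exons with declared
boundaries in a companion BED), so no reference download is needed and
distance-to-exon is exact.  Default mixture per family: 30 common benign
(AF ~ U(0.01, 0.5)), 20 rare benign (AF < 0.001, CADD ~ U(0, 10)), 1
de novo damaging (novel, CADD ~ U(20, 45)), 1 compound-het pair
(AF ~ U(0.0015, 0.0045) — above the dominant ceiling, below the recessive
one, so only trans-aware screening keeps it), and 1 inherited
ClinVar-pathogenic variant; genes land on the panel with probability 0.5
and in the GenCC set with probability 0.5; 5% of benign rows are non-PASS.
Depths are drawn so het balance is comfortably above threshold and GQ
above 40 — the genotype-quality rules are exercised by unit tests, not by
the mixture.  Every variant carries a truth row (category, inheritance
label, expected HiPPo verdict, expected GMS tier) computed by the
generator from the values it drew, independently of the filter code; the
end-to-end tests demand exact agreement.  Output is byte-for-byte
deterministic in the seed.

What passing these tests shows: the rules fire exactly as specified on
cleanly annotated data.  What they do not show: robustness to annotation
noise, multi-gene overlaps, linkage, mosaicism, or caller-specific
artefacts — real cohorts have all of these and the synthetic one has none.

## Numerical and interface choices

* Coordinates are 1-based VCF convention throughout; BED output is the
  only 0-based surface.  Multi-allelic rows are split on ingestion with
  per-allele depths and Number=A annotations resolved by index.
* Quads decompose into one analysis trio per affected child with parents
  duplicated, mirroring clinical sequencing practice.
* "On any transcript" means one qualifying transcript suffices; the
  qualifying consequence is recorded in the rule trail.
* The GQ rule applies to the proband only by default (`gq_all_members`
  extends it to parents) — the protocol does not state which; proband-only
  is the less destructive reading.
* The ±8 bp / ±20 bp windows are genomic distances to the nearest
  annotated exon edge; when an annotation supplies no distance, canonical
  splice terms imply ≤ 2 bp and splice-region terms ≤ 8 bp.
* The annotation transcript set (RefSeq vs Ensembl) is declared in config
  and carried as provenance; no default is asserted as correct.
* All thresholds live in `FilterConfig`; the two strategies ship as two
  presets (`hippo.yaml`, `gms.yaml` under `hippo/data/`), and any override
  is logged.

## Known limitations

No read-backed phasing or mosaicism modelling; no CNV *calling* (only the
Tier A overlap rule); no ACMG/AMP classification of retained variants; no
HPO-based phenotype matching (criterion 2 consumes a human judgement);
Exomiser, CADD, REVEL and SpliceAI are consumed annotations, never
recomputed.  The GMS implementation covers the published filtering and
tier definitions, not full parity with the national tiering software.
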