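# hippo-triage

Trio-aware variant triage for rare-disease sequencing, comparing two
strategies for reducing millions of called variants to a reviewable
candidate list:

* **HiPPo** — a panel-agnostic filter that keeps variants of **Hi**gh
  **P**athogenic **Po**tential anywhere in the coding genome: rare in
  population databases (gnomAD exomes/genomes, TOPMed, ExAC, 1000G) and in
  the joint-called cohort, coding or within ±20 bp of an exon (excluding
  synonymous), CADD > 15, SpliceAI > 0.2 for splicing variants, no
  benign/likely-benign ClinVar assertion, proband allele balance > 0.2 and
  GQ > 40 — with ClinVar P/LP variants retained even when inherited from an
  unaffected parent.
* **GMS tiering** — the panel-based strategy of the NHS Genome Medicine
  Service: after frequency/quality pre-filters (AF < 0.001 dominant /
  < 0.01 recessive, coding ±8 bp non-synonymous, GQ > 30, PASS), variants
  are reviewed only if they fall in a *green* gene of the PanelApp panel(s)
  applied (Tier 1: predicted LoF or de novo; Tier 2: other coding), plus a
  small gene-agnostic channel (de novo coding variants; Exomiser top-3
  ranked with score ≥ 0.95) and a CNV rule (Tier A: > 10 kb overlapping a
  ClinGen pathogenic region or a green panel gene).

The package also implements the trio machinery both strategies need —
de novo / recessive / hemizygous classification and transmission-phased
compound-heterozygote detection — the six reporting exclusion criteria used
to call a retained candidate *reportable*, and the head-to-head efficiency
statistics: **diagnostic and reportable rate per variant assessed**, and
paired Wilcoxon signed-rank tests on per-family assessed counts (normal
approximation with continuity and tie corrections, or exact enumeration).

Who it is for: analysts evaluating filtering strategies on trio exome or
genome data, and anyone who wants a transparent, rule-trail-producing
implementation of panel-agnostic vs panel-based triage to benchmark on
their own (or simulated) cohorts.

## Worked example

Simulate an annotated trio cohort, run both strategies and compare:

```bash
hippo simulate --seed 13 --out-dir fixtures/
hippo filter-hippo --vcf fixtures/cohort.vcf --ped fixtures/cohort.ped --out candidates.tsv
hippo tier-gms --vcf fixtures/cohort.vcf --ped fixtures/cohort.ped \
    --panel fixtures/panel.tsv --out tiers.tsv
```

which prints:

```
retained 12 candidates across 3 trios
35 variants passing filtering across the cohort
```

The simulated cohort (3 trios, 54 proband-carrier sites each) plants
per family one de novo damaging variant, one compound-het pair, one
inherited ClinVar-pathogenic variant, and 50 benign variants. HiPPo retains
exactly the 12 planted causal candidates (4 per trio). The panel strategy
returns 35: it catches the planted variants whose genes happen to be on the
panel, but also tiers the rare *benign* on-panel variants (no in-silico
score filter) and misses every off-panel non-de-novo causal variant —
the efficiency contrast the comparison statistics quantify. Each retained
candidate carries a rule trail (e.g.
`mode:dominant;pass:af;pass:cohort_af;pass:consequence:missense@...;pass:cadd;...`)
recording exactly why it survived, and every run writes a
`*.manifest.json` with input checksums and monotone stage counts.

As a library:

```python
from hippo import FilterConfig, hippo_retain, classify_trio
from hippo.io_formats import read_pedigree, read_trio_vcf

trio = next(iter(read_pedigree("fixtures/cohort.ped").values())).analysis_trios()[0]
for variant, genotypes in read_trio_vcf("fixtures/cohort.vcf", trio):
    label = classify_trio(genotypes, variant.chrom, variant.pos)
    retained, trail = hippo_retain(variant, genotypes, label)
```

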