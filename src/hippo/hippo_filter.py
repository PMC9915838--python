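"""The HiPPo retention rules: panel-agnostic triage for High Pathogenic Potential.

A variant is retained when *all* applicable rules pass — rarity in population
and cohort, a coding (or near-exon) non-synonymous consequence on any
transcript, SpliceAI support for splicing variants, CADD above threshold, no
benign ClinVar assertion, and proband call quality — or when the ClinVar
override fires: asserted pathogenic/likely-pathogenic variants are retained
even when inherited from an unaffected parent, subject only to a population
allele-frequency safety ceiling.

Every decision carries a rule trail (``pass:``/``fail:``/``note:`` entries)
so a reviewer can see exactly why a variant survived.  Absence of an
annotation is never treated as a failing score: a missing CADD value skips
the CADD rule with a ``note:cadd_absent`` entry, because HiPPo is a
sensitivity-first research filter.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from hippo.config import FilterConfig
from hippo.inheritance import (
    InheritanceLabel,
    allele_balance,
    classify_trio,
    find_compound_hets,
)
from hippo.records import AnnotatedVariant, GeneList, Genotype, Trio, TrioGenotypes


def clinvar_override(
    variant: AnnotatedVariant,
    trio: Optional[TrioGenotypes] = None,
    cfg: Optional[FilterConfig] = None,
) -> bool:
    """True iff the variant is asserted P/LP in ClinVar and below the
    override's population-AF safety ceiling.

    When true the variant is retained regardless of inheritance label, score
    thresholds, or presence in unaffected parents.
    """
    cfg = cfg or FilterConfig.hippo()
    if not cfg.clinvar_override:
        return False
    return (
        variant.clinvar.is_path_or_likely
        and variant.max_af < cfg.clinvar_override_af_ceiling
    )


def hippo_retain(
    variant: AnnotatedVariant,
    trio: Optional[TrioGenotypes],
    label: InheritanceLabel,
    cfg: Optional[FilterConfig] = None,
    mode: Optional[str] = None,
) -> tuple[bool, list[str]]:
    """Apply the HiPPo retention rules to one variant.

    ``mode`` selects the dominant or recessive allele-frequency ceilings;
    when omitted it is derived from the inheritance label.  ``trio`` may be
    ``None`` for annotation-only records (e.g. transcribed report tables), in
    which case the genotype-level rules (allele balance, GQ) abstain with a
    trail note.

    Returns ``(retained, trail)``; the trail is always non-empty.
    """
    cfg = cfg or FilterConfig.hippo()
    mode = mode or label.default_mode
    trail: list[str] = [f"mode:{mode}"]

    if clinvar_override(variant, trio, cfg):
        trail.append("pass:clinvar_override_plp")
        trail.append(f"note:af_max={variant.max_af:g}")
        return True, trail
    if variant.clinvar.is_path_or_likely and cfg.clinvar_override:
        trail.append("note:clinvar_override_blocked_by_af_ceiling")

    failed = False

    # (i) population allele frequency, max over sources; absent AF -> 0
    af_ceiling = cfg.af_max(mode)
    if variant.max_af < af_ceiling:
        trail.append("pass:af")
    else:
        trail.append(f"fail:af:{variant.max_af:g}>={af_ceiling:g}")
        failed = True

    # (ii) cohort allele frequency
    if cfg.cohort_af_max is not None:
        cohort = variant.cohort_af if variant.cohort_af is not None else 0.0
        if cohort < cfg.cohort_af_max:
            trail.append("pass:cohort_af")
        else:
            trail.append(f"fail:cohort_af:{cohort:g}>={cfg.cohort_af_max:g}")
            failed = True

    # (iii) locational rule: coding +/- window, excluding synonymous, on any
    # transcript
    quals = variant.qualifying_consequences(cfg.coding_window_bp)
    if quals:
        best = quals[0]
        trail.append(f"pass:consequence:{best.canonical}@{best.transcript_id}")
    else:
        trail.append("fail:consequence")
        failed = True

    # (iv) SpliceAI for splicing variants: applies only when no coding
    # consequence qualifies
    if cfg.spliceai_min is not None and quals and not any(c.is_coding for c in quals):
        if variant.spliceai is not None:
            if variant.spliceai > cfg.spliceai_min:
                trail.append("pass:spliceai")
            else:
                trail.append(
                    f"fail:spliceai:{variant.spliceai:g}<={cfg.spliceai_min:g}"
                )
                failed = True
        elif any(c.is_canonical_splice for c in quals):
            # canonical-splice-site disruption with no score: predicted LoF
            trail.append("note:canonical_splice_spliceai_absent")
        else:
            trail.append("note:spliceai_absent")

    # (v) CADD, when a score is present
    if cfg.cadd_min is not None:
        if variant.cadd is None:
            trail.append("note:cadd_absent")
        elif variant.cadd > cfg.cadd_min:
            trail.append("pass:cadd")
        else:
            trail.append(f"fail:cadd:{variant.cadd:g}<={cfg.cadd_min:g}")
            failed = True

    # (vi) remove benign / likely benign ClinVar assertions
    if cfg.remove_benign:
        if variant.clinvar.is_benign_or_likely:
            trail.append(f"fail:clinvar_benign:{variant.clinvar.value}")
            failed = True
        else:
            trail.append("pass:clinvar")

    # (vii) proband allele balance on het calls
    # (viii) genotype quality
    if trio is None or trio.proband is None:
        trail.append("note:genotype_rules_skipped")
    else:
        pro = trio.proband
        if cfg.allele_balance_min is not None and pro.genotype is Genotype.HET:
            ab = allele_balance(pro)
            if ab > cfg.allele_balance_min:
                trail.append("pass:allele_balance")
            else:
                trail.append(
                    f"fail:allele_balance:{ab:g}<={cfg.allele_balance_min:g}"
                )
                failed = True
        if cfg.gq_min is not None:
            members = [("proband", pro)]
            if cfg.gq_all_members:
                members += [("mother", trio.mother), ("father", trio.father)]
            for role, m in members:
                if m is None or m.genotype is Genotype.MISSING:
                    continue
                if m.gq is None:
                    trail.append(f"note:gq_absent:{role}")
                elif m.gq > cfg.gq_min:
                    trail.append(f"pass:gq:{role}")
                else:
                    trail.append(f"fail:gq:{role}:{m.gq}<={cfg.gq_min}")
                    failed = True

    return (not failed), trail


# ---------------------------------------------------------------------------
# Candidate sets
# ---------------------------------------------------------------------------


@dataclass
class Candidate:
    """One retained variant with the evidence trail that retained it."""

    variant: AnnotatedVariant
    label: InheritanceLabel
    mode: str
    trail: list[str]
    trio: Optional[TrioGenotypes] = None
    comp_het_partner: Optional[tuple[str, int, str, str]] = None

    @property
    def is_comp_het(self) -> bool:
        return self.comp_het_partner is not None


@dataclass
class CandidateSet:
    """All variants a strategy retained for one family."""

    family_id: str
    strategy: str
    candidates: list[Candidate] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.candidates:
            if not c.trail:
                raise ValueError(
                    f"candidate {c.variant.key} has an empty rule trail"
                )

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {c.variant.key for c in self.candidates}

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.candidates:
            out |= c.variant.genes()
        return out


def restrict_to_genes(candidates: CandidateSet, genes: GeneList) -> CandidateSet:
    """Subset a candidate set to variants whose gene (on any qualifying
    transcript) is in the supplied list.  Always a subset of the input."""
    kept = [c for c in candidates if c.variant.genes() & genes.symbols]
    return CandidateSet(
        family_id=candidates.family_id,
        strategy=f"{candidates.strategy}|{genes.name}",
        candidates=kept,
    )


# ---------------------------------------------------------------------------
# Per-trio pipeline
# ---------------------------------------------------------------------------


def run_hippo(
    records: Sequence[tuple[AnnotatedVariant, TrioGenotypes]],
    trio: Trio,
    cfg: Optional[FilterConfig] = None,
    gene_list: Optional[GeneList] = None,
) -> CandidateSet:
    """Run the full HiPPo triage on one trio's variant stream.

    Classifies inheritance, detects compound-heterozygous pairs per gene
    (partners are re-screened under the recessive thresholds), applies the
    retention rules, and optionally restricts the result to a gene list.
    """
    cfg = cfg or FilterConfig.hippo()

    # only proband-carrier sites are candidates (joint-called VCFs carry
    # every cohort member's variants at every sample column)
    labelled = [
        (v, g, classify_trio(g, v.chrom, v.pos, trio.proband_sex))
        for v, g in records
        if g.proband is not None and g.proband.genotype.carries_alt
    ]

    # compound-het pairing per gene
    by_gene: dict[str, list[tuple[AnnotatedVariant, TrioGenotypes, InheritanceLabel]]]
    by_gene = defaultdict(list)
    for v, g, label in labelled:
        for gene in v.genes():
            by_gene[gene].append((v, g, label))
    partner_of: dict[tuple, set[tuple]] = defaultdict(set)
    for gene_records in by_gene.values():
        for v1, v2 in find_compound_hets(gene_records):
            partner_of[v1.key].add(v2.key)
            partner_of[v2.key].add(v1.key)

    # retention: default mode first, recessive re-screen for paired hets
    passed: dict[tuple, Candidate] = {}
    for v, g, label in labelled:
        retained, trail = hippo_retain(v, g, label, cfg)
        mode = label.default_mode
        if not retained and v.key in partner_of and mode != "recessive":
            retained, trail = hippo_retain(v, g, label, cfg, mode="recessive")
            mode = "recessive"
        if retained:
            passed[v.key] = Candidate(
                variant=v, label=label, mode=mode, trail=trail, trio=g
            )

    # a comp-het pair only counts when both members were retained
    for key, cand in passed.items():
        partners = [p for p in partner_of.get(key, ()) if p in passed]
        if partners:
            cand.comp_het_partner = sorted(partners)[0]
            cand.trail.append("note:comp_het_partner")

    out = CandidateSet(
        family_id=trio.family_id,
        strategy="hippo",
        candidates=sorted(
            passed.values(), key=lambda c: (c.variant.chrom, c.variant.pos)
        ),
    )
    if gene_list is not None:
        out = restrict_to_genes(out, gene_list)
    return out
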