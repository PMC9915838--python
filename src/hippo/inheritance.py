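"""Trio segregation: per-variant inheritance labels and compound-het pairing.

The classifier assigns exactly one label per (variant, proband); the
compound-het finder then marks qualifying heterozygous pairs within a gene.
De novo calls are deliberately conservative: both parents must have genotype
data present and be homozygous reference — a site with a missing parental
genotype is retained but can never be labelled de novo.
"""

from __future__ import annotations

import enum
import itertools
from typing import Optional, Sequence

from hippo.records import AnnotatedVariant, Genotype, MemberGenotype, TrioGenotypes

#: GRCh38 pseudo-autosomal regions on X (1-based inclusive).
GRCH38_X_PARS: tuple[tuple[int, int], ...] = ((10_001, 2_781_479), (155_701_383, 156_030_895))

_X_NAMES = {"x", "chrx"}


class InheritanceLabel(enum.Enum):
    DE_NOVO = "de_novo"
    INHERITED_HET_MAT = "inherited_het_mat"
    INHERITED_HET_PAT = "inherited_het_pat"
    HOM_RECESSIVE = "hom_recessive"
    HEMIZYGOUS = "hemizygous"
    UNINFORMATIVE = "uninformative"

    @property
    def is_inherited_het(self) -> bool:
        return self in (
            InheritanceLabel.INHERITED_HET_MAT,
            InheritanceLabel.INHERITED_HET_PAT,
        )

    @property
    def default_mode(self) -> str:
        """Which search (dominant vs recessive) a label feeds by default.

        Homozygous and hemizygous genotypes belong to the recessive search;
        everything else — de novo, inherited hets awaiting a trans partner,
        uninformative sites — is screened under the dominant thresholds.
        Compound-het partners are re-screened under the recessive mode by the
        pipeline once pairing is established.
        """
        if self in (InheritanceLabel.HOM_RECESSIVE, InheritanceLabel.HEMIZYGOUS):
            return "recessive"
        return "dominant"


def _is_x_nonpar(
    chrom: str, pos: Optional[int], pars: Sequence[tuple[int, int]]
) -> bool:
    if chrom.lower() not in _X_NAMES:
        return False
    if pos is None:
        return True
    return not any(start <= pos <= end for start, end in pars)


def _present(member: Optional[MemberGenotype]) -> bool:
    return member is not None and member.genotype is not Genotype.MISSING


def classify_trio(
    trio: TrioGenotypes,
    chrom: str = "1",
    pos: Optional[int] = None,
    proband_sex: Optional[str] = None,
    pars: Sequence[tuple[int, int]] = GRCH38_X_PARS,
) -> InheritanceLabel:
    """Assign a single segregation label to one site in one trio.

    Rules, in precedence order:

    * ``de_novo`` — proband carries at least one alt allele and *both*
      parents have genotype data present and are homozygous reference.
    * ``hemizygous`` — X non-PAR site, male proband carrying alt, mother
      heterozygous, father a non-carrier (hom-ref or absent).
    * ``hom_recessive`` — proband homozygous alt and each parent with data
      carries at most one alt allele.
    * ``inherited_het_mat`` / ``inherited_het_pat`` — proband het with
      exactly one carrier parent (a parent without genotype data cannot be
      the attributed carrier).
    * ``uninformative`` — everything else, including a missing proband
      genotype, a non-carrier proband, and an unphaseable het where both
      parents carry the allele.
    """
    pro = trio.proband
    if not _present(pro):
        return InheritanceLabel.UNINFORMATIVE
    pg = pro.genotype
    if not pg.carries_alt:
        return InheritanceLabel.UNINFORMATIVE

    mother, father = trio.mother, trio.father
    mother_present, father_present = _present(mother), _present(father)
    mg = mother.genotype if mother_present else None
    fg = father.genotype if father_present else None

    if mother_present and father_present and mg is Genotype.HOM_REF and fg is Genotype.HOM_REF:
        return InheritanceLabel.DE_NOVO

    if (
        _is_x_nonpar(chrom, pos, pars)
        and proband_sex == "male"
        and mg is Genotype.HET
        and (father is None or not father_present or fg is Genotype.HOM_REF)
    ):
        return InheritanceLabel.HEMIZYGOUS

    if pg is Genotype.HOM_ALT:
        parents_ok = all(
            g.alt_count <= 1 for g in (mg, fg) if g is not None
        )
        if parents_ok:
            return InheritanceLabel.HOM_RECESSIVE
        return InheritanceLabel.UNINFORMATIVE

    if pg in (Genotype.HET, Genotype.HEMI):
        mat_carrier = mg.carries_alt if mg is not None else False
        pat_carrier = fg.carries_alt if fg is not None else False
        if mat_carrier and not pat_carrier:
            return InheritanceLabel.INHERITED_HET_MAT
        if pat_carrier and not mat_carrier:
            return InheritanceLabel.INHERITED_HET_PAT
        # both carriers: transmission side unknowable without phasing;
        # neither carrier with a parent missing: could be de novo or inherited
        return InheritanceLabel.UNINFORMATIVE

    return InheritanceLabel.UNINFORMATIVE


def allele_balance(member: MemberGenotype) -> float:
    """Fraction of reads supporting the alt allele.

    Zero total depth returns 0.0, which fails any strict ``> t`` balance
    threshold — a het call with no supporting reads is treated as failing.
    """
    total = member.ref_reads + member.alt_reads
    if total == 0:
        return 0.0
    return member.alt_reads / total


def find_compound_hets(
    variants_in_gene: Sequence[tuple[AnnotatedVariant, TrioGenotypes, InheritanceLabel]],
) -> list[tuple[AnnotatedVariant, AnnotatedVariant]]:
    """Heterozygous pairs in trans within one gene, by transmission phasing.

    A pair qualifies iff one member is maternally and the other paternally
    inherited, or one member is an (unphased) de novo het and the other an
    inherited het — a de novo cannot be proven cis with either haplotype.
    Two variants transmitted by the same parent never pair, and a variant
    never pairs with itself.  Pair order follows input order.
    """
    het_records = [
        (v, label)
        for v, trio, label in variants_in_gene
        if trio.proband is not None and trio.proband.genotype is Genotype.HET
    ]
    pairs = []
    for (v1, l1), (v2, l2) in itertools.combinations(het_records, 2):
        labels = {l1, l2}
        trans = labels == {
            InheritanceLabel.INHERITED_HET_MAT,
            InheritanceLabel.INHERITED_HET_PAT,
        }
        de_novo_mix = (
            InheritanceLabel.DE_NOVO in labels
            and any(l.is_inherited_het for l in labels)
        )
        if trans or de_novo_mix:
            pairs.append((v1, v2))
    return pairs
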