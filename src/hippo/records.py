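"""Normalised domain records shared by every stage of the toolkit.

All coordinates are 1-based VCF convention throughout; there is no internal
0-based layer.  After normalisation every :class:`AnnotatedVariant` is
bi-allelic — multi-allelic input rows are split upstream by the readers in
:mod:`hippo.io_formats`.

A deliberately maintained distinction: *absent* annotations are ``None``,
never 0.  A variant with no CADD score is not a variant with CADD 0, and the
filters treat the two differently (absence of evidence is not evidence of
benignity).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class ClinVarStatus(enum.Enum):
    """Aggregate ClinVar assertion for a variant."""

    PATHOGENIC = "P"
    LIKELY_PATHOGENIC = "LP"
    VUS = "VUS"
    LIKELY_BENIGN = "LB"
    BENIGN = "B"
    CONFLICTING = "conflicting"
    ABSENT = "absent"

    @classmethod
    def parse(cls, raw: Optional[str]) -> "ClinVarStatus":
        """Map free-text ClinVar significance strings onto the enum.

        Handles both the short codes used in sidecar tables (``P``, ``LP``)
        and the underscore-joined CLNSIG vocabulary
        (``Likely_pathogenic``, ``Benign/Likely_benign`` ...).
        """
        if raw is None:
            return cls.ABSENT
        text = str(raw).strip()
        if not text or text == ".":
            return cls.ABSENT
        key = text.lower().replace(" ", "_")
        direct = {
            "p": cls.PATHOGENIC,
            "pathogenic": cls.PATHOGENIC,
            "lp": cls.LIKELY_PATHOGENIC,
            "likely_pathogenic": cls.LIKELY_PATHOGENIC,
            "pathogenic/likely_pathogenic": cls.PATHOGENIC,
            "vus": cls.VUS,
            "uncertain_significance": cls.VUS,
            "lb": cls.LIKELY_BENIGN,
            "likely_benign": cls.LIKELY_BENIGN,
            "b": cls.BENIGN,
            "benign": cls.BENIGN,
            "benign/likely_benign": cls.BENIGN,
            "conflicting": cls.CONFLICTING,
            "conflicting_interpretations_of_pathogenicity": cls.CONFLICTING,
            "conflicting_classifications_of_pathogenicity": cls.CONFLICTING,
            "absent": cls.ABSENT,
        }
        if key in direct:
            return direct[key]
        raise ValueError(f"unrecognised ClinVar significance: {raw!r}")

    @property
    def is_path_or_likely(self) -> bool:
        return self in (ClinVarStatus.PATHOGENIC, ClinVarStatus.LIKELY_PATHOGENIC)

    @property
    def is_benign_or_likely(self) -> bool:
        return self in (ClinVarStatus.BENIGN, ClinVarStatus.LIKELY_BENIGN)


# ---------------------------------------------------------------------------
# Consequence vocabulary
# ---------------------------------------------------------------------------

#: VEP-style terms reduced to a canonical short form (``_variant`` stripped).
_TERM_ALIASES = {
    "intronic": "intron",
    "nonsense": "stop_gained",
    "stop_gain": "stop_gained",
    "5_prime_utr": "utr_5",
    "3_prime_utr": "utr_3",
    "initiator_codon": "start_lost",
    "splice_donor_5th_base": "splice_region",
    "splice_donor_region": "splice_region",
    "splice_polypyrimidine_tract": "splice_region",
}

CODING_TERMS = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering",
        "coding_sequence",
        "synonymous",
        "stop_retained",
        "start_retained",
    }
)

SYNONYMOUS_TERMS = frozenset({"synonymous", "stop_retained", "start_retained"})

#: Near-exon terms eligible for the +/- window rule.
SPLICE_OR_INTRONIC_TERMS = frozenset(
    {"splice_donor", "splice_acceptor", "splice_region", "intron"}
)

CANONICAL_SPLICE_TERMS = frozenset({"splice_donor", "splice_acceptor"})

#: Default predicted loss-of-function set (configurable in FilterConfig).
DEFAULT_PLOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift",
        "splice_donor",
        "splice_acceptor",
        "start_lost",
        "stop_lost",
    }
)

#: Implicit distance to the nearest exon edge when the annotation source
#: supplies none: canonical splice sites are within 2 bp by definition and
#: splice-region annotations within 8 bp.
_IMPLICIT_DISTANCE = {"splice_donor": 2, "splice_acceptor": 2, "splice_region": 8}


def canonical_term(term: str) -> str:
    """Reduce a consequence term to its canonical short form."""
    t = term.strip().lower()
    if t.endswith("_variant"):
        t = t[: -len("_variant")]
    return _TERM_ALIASES.get(t, t)


@dataclass(frozen=True)
class TranscriptConsequence:
    """One predicted consequence of a variant on one transcript."""

    transcript_id: str
    term: str
    #: Genomic distance (bp) to the nearest annotated exon edge; 0 for exonic
    #: consequences, ``None`` when the annotation source supplied none.
    distance_to_exon: Optional[int] = None
    gene: Optional[str] = None

    @property
    def canonical(self) -> str:
        return canonical_term(self.term)

    @property
    def is_coding(self) -> bool:
        return self.canonical in CODING_TERMS

    @property
    def is_synonymous(self) -> bool:
        return self.canonical in SYNONYMOUS_TERMS

    @property
    def is_splice_or_intronic(self) -> bool:
        return self.canonical in SPLICE_OR_INTRONIC_TERMS

    @property
    def is_canonical_splice(self) -> bool:
        return self.canonical in CANONICAL_SPLICE_TERMS

    def effective_distance(self) -> Optional[int]:
        """Distance to exon, falling back to the term-implied bound."""
        if self.distance_to_exon is not None:
            return abs(self.distance_to_exon)
        if self.is_coding:
            return 0
        return _IMPLICIT_DISTANCE.get(self.canonical)

    def qualifies(self, window_bp: int) -> bool:
        """Does this consequence satisfy the "coding +/- N bp, excluding
        synonymous" locational rule for the given window?"""
        if self.is_synonymous:
            return False
        if self.is_coding:
            return True
        if self.is_splice_or_intronic:
            dist = self.effective_distance()
            return dist is not None and dist <= window_bp
        return False


@dataclass
class AnnotatedVariant:
    """One normalised, bi-allelic variant with its consumed annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    consequences: list[TranscriptConsequence] = field(default_factory=list)
    #: population source name -> allele fraction in [0, 1]
    af_sources: dict[str, float] = field(default_factory=dict)
    cohort_af: Optional[float] = None
    cadd: Optional[float] = None
    revel: Optional[float] = None
    spliceai: Optional[float] = None
    clinvar: ClinVarStatus = ClinVarStatus.ABSENT
    exomiser_rank: Optional[int] = None
    exomiser_score: Optional[float] = None
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for name, af in self.af_sources.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele fraction {name}={af} outside [0, 1]")
        if self.cohort_af is not None and not 0.0 <= self.cohort_af <= 1.0:
            raise ValueError(f"cohort_af={self.cohort_af} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site identity used for overlap and evidence joins."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_af(self) -> float:
        """Maximum allele fraction over population sources; 0 when none
        reported (a never-seen variant is treated as novel)."""
        return max(self.af_sources.values(), default=0.0)

    def qualifying_consequences(self, window_bp: int) -> list[TranscriptConsequence]:
        """Transcript consequences passing the locational rule at ``window_bp``
        ("on any transcript": one qualifying transcript is enough)."""
        return [c for c in self.consequences if c.qualifies(window_bp)]

    def genes(self) -> set[str]:
        """Every gene symbol attached to this variant (top level + per
        transcript)."""
        out = {c.gene for c in self.consequences if c.gene}
        if self.gene:
            out.add(self.gene)
        return out

    @property
    def is_plof(self) -> bool:
        return any(c.canonical in DEFAULT_PLOF_TERMS for c in self.consequences)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"
    MISSING = "missing"

    @property
    def alt_count(self) -> int:
        """Alt allele dosage (hemizygous alt counts as 1)."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "hemi": 1, "missing": 0}[
            self.value
        ]

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI)


@dataclass
class MemberGenotype:
    """One sample's call at one site."""

    genotype: Genotype = Genotype.MISSING
    ref_reads: int = 0
    alt_reads: int = 0
    gq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("allele depths must be >= 0")
        if self.gq is not None and self.gq < 0:
            raise ValueError("genotype quality must be >= 0")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass
class TrioGenotypes:
    """Proband plus (optionally) parents at one site.

    A ``None`` member means that person was never sequenced (duo support); a
    member with :attr:`MemberGenotype.genotype` ``MISSING`` was sequenced but
    uncalled at this site.  The two are treated the same way by the
    inheritance classifier but the distinction is preserved for reporting.
    """

    proband: Optional[MemberGenotype] = None
    mother: Optional[MemberGenotype] = None
    father: Optional[MemberGenotype] = None

    def member(self, role: str) -> Optional[MemberGenotype]:
        return getattr(self, role)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass
class PedigreeMember:
    individual_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Optional[str] = None  # "male" / "female" / None (unknown)
    affected: Optional[bool] = None  # None = unknown


@dataclass
class Pedigree:
    """One family's members, with trio decomposition for analysis.

    Quads (two affected children, shared parents) are decomposed into one
    analysis trio per affected child with the parents duplicated, mirroring
    clinical practice where quads are sequenced as two separate trios.
    """

    family_id: str
    members: dict[str, PedigreeMember] = field(default_factory=dict)

    def add(self, member: PedigreeMember) -> None:
        self.members[member.individual_id] = member

    def validate(self) -> None:
        """Check parent references resolve and parentage is acyclic."""
        for m in self.members.values():
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self.members:
                    raise ValueError(
                        f"family {self.family_id}: member {m.individual_id} "
                        f"references unknown parent {pid}"
                    )
        for start in self.members:
            seen = set()
            stack = [start]
            while stack:
                node = stack.pop()
                if node in seen:
                    raise ValueError(
                        f"family {self.family_id}: cyclic parentage involving {node}"
                    )
                seen.add(node)
                m = self.members[node]
                stack.extend(p for p in (m.father_id, m.mother_id) if p is not None)

    def affected_children(self) -> list[PedigreeMember]:
        return [
            m
            for m in self.members.values()
            if m.affected and (m.father_id or m.mother_id)
        ]

    def analysis_trios(self) -> list["Trio"]:
        """One trio per affected child; parents duplicated for quads."""
        trios = []
        for child in self.affected_children():
            trios.append(
                Trio(
                    family_id=self.family_id,
                    proband_id=child.individual_id,
                    father_id=child.father_id,
                    mother_id=child.mother_id,
                    proband_sex=child.sex,
                )
            )
        return trios


@dataclass(frozen=True)
class Trio:
    """One analysis unit: a proband and their (possibly absent) parents."""

    family_id: str
    proband_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    proband_sex: Optional[str] = None

    def sample_ids(self) -> list[str]:
        return [
            s for s in (self.proband_id, self.mother_id, self.father_id) if s
        ]


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

GENE_LIST_PROVENANCES = ("panelapp_green", "gencc_strong_definitive", "custom")


@dataclass
class GeneList:
    """A named set of gene symbols with its provenance.

    ``panelapp_green`` lists contain only diagnostic-grade (green) panel
    genes; ``gencc_strong_definitive`` lists contain only genes whose
    gene-disease validity is classified Strong or Definitive by the Gene
    Curation Coalition.
    """

    name: str
    symbols: frozenset[str]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        if self.provenance not in GENE_LIST_PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if any(not s or not s.strip() for s in self.symbols):
            raise ValueError("gene symbols must be non-empty strings")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    @staticmethod
    def union(lists: Iterable["GeneList"], name: str = "union") -> "GeneList":
        syms: set[str] = set()
        for gl in lists:
            syms |= gl.symbols
        return GeneList(name=name, symbols=frozenset(syms), provenance="custom")
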