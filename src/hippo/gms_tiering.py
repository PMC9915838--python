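"""The GMS panel-based strategy: pre-filters, tiering, and the Tier A CNV rule.

The NHS Genome Medicine Service restricts review of short variants to
``green`` (diagnostic-grade) genes on the PanelApp panel(s) the referring
clinician selected.  After a quality/frequency pre-filter, variants are
tiered:

* **Tier 1** — predicted loss-of-function or de novo variants in a green
  panel gene;
* **Tier 2** — other coding variants within +/- 8 bp of an exon (excluding
  synonymous), on any transcript, in a green panel gene;
* **gene-agnostic channel** — any de novo coding variant, and Exomiser
  top-3-ranked variants with score >= 0.95, in any gene; these bypass the
  genotype-quality and PASS pre-filters;
* **Tier A** — CNVs larger than 10 kb overlapping a ClinGen curated
  pathogenic region or a green panel gene.

Synonymous variants are never tiered, even when predicted to affect
splicing.  Everything else is UNTIERED and not returned for review — which
is how an asserted-pathogenic variant in an off-panel gene is missed.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from hippo.config import FilterConfig
from hippo.inheritance import InheritanceLabel, classify_trio
from hippo.records import AnnotatedVariant, GeneList, Genotype, Trio, TrioGenotypes

log = logging.getLogger(__name__)


class Tier(enum.Enum):
    TIER1 = "TIER1"
    TIER2 = "TIER2"
    GENE_AGNOSTIC_DENOVO = "GENE_AGNOSTIC_DENOVO"
    GENE_AGNOSTIC_EXOMISER = "GENE_AGNOSTIC_EXOMISER"
    UNTIERED = "UNTIERED"


#: reporting precedence: a variant holding several qualifications is
#: reported once under the highest.
_PRECEDENCE = [
    Tier.TIER1,
    Tier.TIER2,
    Tier.GENE_AGNOSTIC_DENOVO,
    Tier.GENE_AGNOSTIC_EXOMISER,
]


@dataclass
class TierAssignment:
    variant: AnnotatedVariant
    tier: Tier
    #: the panel whose green-gene membership triggered a panel tier
    panel: Optional[str] = None
    #: every qualification held, including ones below the reported tier
    flags: frozenset[Tier] = frozenset()
    label: InheritanceLabel = InheritanceLabel.UNINFORMATIVE

    @property
    def passing(self) -> bool:
        """Returned for laboratory review (counted as 'passing filtering')."""
        return self.tier is not Tier.UNTIERED


def _is_plof(variant: AnnotatedVariant, cfg: FilterConfig) -> bool:
    return any(c.canonical in cfg.plof_terms for c in variant.consequences)


def _coding_nonsyn(variant: AnnotatedVariant, window_bp: int) -> bool:
    return bool(variant.qualifying_consequences(window_bp))


def gene_agnostic_flags(
    variant: AnnotatedVariant,
    label: InheritanceLabel,
    cfg: Optional[FilterConfig] = None,
) -> set[Tier]:
    """Gene-agnostic channel membership: de novo coding variants and
    Exomiser top-ranked variants.  Absent Exomiser annotations mean not
    eligible."""
    cfg = cfg or FilterConfig.gms()
    flags: set[Tier] = set()
    if label is InheritanceLabel.DE_NOVO and _coding_nonsyn(
        variant, cfg.coding_window_bp
    ):
        flags.add(Tier.GENE_AGNOSTIC_DENOVO)
    if (
        variant.exomiser_rank is not None
        and variant.exomiser_score is not None
        and variant.exomiser_rank <= cfg.exomiser_rank_max
        and variant.exomiser_score >= cfg.exomiser_score_min
    ):
        flags.add(Tier.GENE_AGNOSTIC_EXOMISER)
    return flags


def gms_prefilter(
    variant: AnnotatedVariant,
    trio: Optional[TrioGenotypes],
    label: InheritanceLabel,
    cfg: Optional[FilterConfig] = None,
    mode: Optional[str] = None,
) -> bool:
    """The GMS quality/frequency pre-filter.

    Passes iff the maximum population AF is below the mode threshold
    (0.001 dominant / 0.01 recessive), some transcript consequence is coding
    within +/- 8 bp and not synonymous, proband GQ > 30 and FILTER is PASS.
    Gene-agnostic candidates bypass the GQ and PASS requirements (they are
    "not filtered on quality") but not the AF or consequence rules.
    """
    cfg = cfg or FilterConfig.gms()
    mode = mode or label.default_mode

    if variant.max_af >= cfg.af_max(mode):
        return False
    if not _coding_nonsyn(variant, cfg.coding_window_bp):
        return False

    if gene_agnostic_flags(variant, label, cfg):
        return True

    if cfg.require_pass and variant.filter_status != "PASS":
        return False
    if cfg.gq_min is not None and trio is not None and trio.proband is not None:
        gq = trio.proband.gq
        if gq is not None and gq <= cfg.gq_min:
            return False
    return True


def assign_tier(
    variant: AnnotatedVariant,
    label: InheritanceLabel,
    panels: Sequence[GeneList],
    cfg: Optional[FilterConfig] = None,
) -> TierAssignment:
    """Tier one pre-filtered variant against the applied panels.

    With no panels supplied only the gene-agnostic tiers are reachable (a
    warning is logged once per call site).
    """
    cfg = cfg or FilterConfig.gms()
    if not panels:
        log.warning("no panels supplied: only gene-agnostic tiers possible")

    flags: set[Tier] = set(gene_agnostic_flags(variant, label, cfg))
    triggering_panel: Optional[str] = None

    genes = variant.genes()
    green_panel = next(
        (p for p in panels if genes & p.symbols), None
    )
    if green_panel is not None:
        coding = _coding_nonsyn(variant, cfg.coding_window_bp)
        if (_is_plof(variant, cfg) or label is InheritanceLabel.DE_NOVO) and coding:
            flags.add(Tier.TIER1)
        if coding:
            flags.add(Tier.TIER2)
        triggering_panel = green_panel.name

    tier = next((t for t in _PRECEDENCE if t in flags), Tier.UNTIERED)
    return TierAssignment(
        variant=variant,
        tier=tier,
        panel=triggering_panel if tier in (Tier.TIER1, Tier.TIER2) else None,
        flags=frozenset(flags),
        label=label,
    )


def run_gms(
    records: Sequence[tuple[AnnotatedVariant, TrioGenotypes]],
    trio: Trio,
    panels: Sequence[GeneList],
    cfg: Optional[FilterConfig] = None,
) -> list[TierAssignment]:
    """Run the GMS strategy on one trio's variant stream.

    Returns one assignment per variant that passed the pre-filter (or its
    gene-agnostic bypass); assignments with tier UNTIERED passed the
    pre-filter but were not returned for review.
    """
    cfg = cfg or FilterConfig.gms()
    out = []
    for v, g in records:
        if g.proband is None or not g.proband.genotype.carries_alt:
            continue
        label = classify_trio(g, v.chrom, v.pos, trio.proband_sex)
        if gms_prefilter(v, g, label, cfg):
            out.append(assign_tier(v, label, panels, cfg))
    return out


# ---------------------------------------------------------------------------
# Tier A: CNVs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvRecord:
    """One copy-number variant call (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    copy_number_class: str = "loss"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"CNV end {self.end} < start {self.start}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


class GenomicIntervals:
    """Per-chromosome interval index over 1-based inclusive regions."""

    def __init__(
        self, regions: Iterable[tuple[str, int, int]] = ()
    ) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, start, end in regions:
            # IntervalTree is half-open; +1 makes the inclusive end queryable
            self._trees[chrom].addi(start, end + 1)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """>= 1 shared base with any stored region."""
        return bool(self._trees[chrom].overlap(start, end + 1))


def tier_a_cnv(
    cnv: CnvRecord,
    panel_gene_intervals: GenomicIntervals,
    clingen_regions: Optional[GenomicIntervals] = None,
    cfg: Optional[FilterConfig] = None,
) -> bool:
    """The Tier A rule: a CNV larger than the size threshold (10 kb) that
    overlaps (by at least one base) a ClinGen curated pathogenic region or a
    green gene on an applied panel."""
    cfg = cfg or FilterConfig.gms()
    if cnv.size <= cfg.cnv_min_size_bp:
        return False
    if panel_gene_intervals.overlaps(cnv.chrom, cnv.start, cnv.end):
        return True
    if clingen_regions is not None and clingen_regions.overlaps(
        cnv.chrom, cnv.start, cnv.end
    ):
        return True
    return False
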