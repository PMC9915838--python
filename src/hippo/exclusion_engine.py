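"""Reporting exclusions: declarative rules deciding reportable vs excluded.

Candidates surviving a triage strategy are curated before being returned to
the referring clinician.  Six exclusion criteria are applied, in fixed
order; the first that fires is recorded as the primary criterion:

1. heterozygous in a known autosomal-recessive disease gene with no second
   hit identified (coding or non-coding);
2. in a known disease gene whose phenotype does not match the patient's, and
   the variant is not P/LP in ClinVar;
3. in a known disease gene poorly expressed in the relevant tissue (GTEx) or
   exon (pext);
4. in a novel gene that is poorly expressed in the relevant tissue or
   explicitly not involved in the relevant biological pathway;
5. a predicted loss-of-function variant manually curated as not LoF /
   likely not LoF;
6. artefactual on read-level visualisation.

The human-judgement inputs (phenotype match, expression adequacy, pathway
involvement, LoF curation, IGV review) are consumed as evidence flags —
the engine records them, it never guesses them.  An ``unknown`` flag makes
the corresponding rule *abstain*: unknown never auto-resolves to false, so
missing evidence can only leave a candidate reportable, never exclude it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from hippo.hippo_filter import Candidate, CandidateSet
from hippo.records import ClinVarStatus, Genotype

LOF_CURATION_VALUES = ("LoF", "likely_LoF", "not_LoF", "likely_not_LoF", "n/a")
MOI_VALUES = ("AD", "AR", "XL", "none-known")

#: default expression-adequacy cut-offs (package choices; the underlying
#: resources publish no canonical thresholds)
DEFAULT_TPM_MIN = 1.0
DEFAULT_PEXT_MIN = 0.1


def expression_adequate(
    tpm: Optional[float] = None,
    pext: Optional[float] = None,
    tpm_min: float = DEFAULT_TPM_MIN,
    pext_min: float = DEFAULT_PEXT_MIN,
) -> tuple[Optional[bool], Optional[bool]]:
    """Convert raw GTEx tissue TPM and per-base pext values to the tri-state
    adequacy flags of :class:`EvidenceBundle` (``None`` stays unknown)."""
    tissue = None if tpm is None else tpm >= tpm_min
    exon = None if pext is None else pext >= pext_min
    return tissue, exon


@dataclass
class EvidenceBundle:
    """Curation evidence for one candidate.  ``None`` means unknown."""

    gene_disease_moi: str = "none-known"
    second_hit_present: Optional[bool] = None
    phenotype_match: Optional[bool] = None
    tissue_expression_adequate: Optional[bool] = None
    exon_expression_adequate: Optional[bool] = None
    pathway_excluded: Optional[bool] = None
    lof_curation: str = "n/a"
    igv_artefact: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gene_disease_moi not in MOI_VALUES:
            raise ValueError(f"unknown MOI {self.gene_disease_moi!r}")
        if self.lof_curation not in LOF_CURATION_VALUES:
            raise ValueError(f"unknown LoF curation {self.lof_curation!r}")

    @property
    def known_disease_gene(self) -> bool:
        return self.gene_disease_moi != "none-known"


@dataclass
class ReportDecision:
    verdict: str  # "reportable" | "excluded"
    criterion: Optional[int] = None  # 1-6 when excluded (lowest index wins)
    abstained: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict == "excluded" and self.criterion not in range(1, 7):
            raise ValueError("excluded verdicts must carry a criterion 1-6")
        if self.verdict == "reportable" and self.criterion is not None:
            raise ValueError("reportable verdicts carry no criterion")


def evaluate_exclusions(
    candidate: Candidate,
    evidence: EvidenceBundle,
) -> ReportDecision:
    """Map one retained candidate to reportable / excluded(criterion).

    The inheritance label and comp-het pairing come from the candidate; the
    curation judgements come from the evidence bundle.  Rules whose evidence
    is unknown abstain and are listed in the decision.
    """
    abstained: list[str] = []
    v = candidate.variant
    het = (
        candidate.trio is not None
        and candidate.trio.proband is not None
        and candidate.trio.proband.genotype is Genotype.HET
    )

    # 1: lone het in a recessive gene with no second hit
    if het and evidence.gene_disease_moi == "AR" and not candidate.is_comp_het:
        if evidence.second_hit_present is None:
            abstained.append("second_hit")
        elif evidence.second_hit_present is False:
            return ReportDecision("excluded", 1, abstained)

    # 2: phenotype mismatch in a known disease gene, unless ClinVar P/LP
    if evidence.known_disease_gene and not v.clinvar.is_path_or_likely:
        if evidence.phenotype_match is None:
            abstained.append("phenotype_match")
        elif evidence.phenotype_match is False:
            return ReportDecision("excluded", 2, abstained)

    # 3: known disease gene, inadequate tissue or exon expression
    # (fires on any False; abstains while an unknown field could still fire it)
    if evidence.known_disease_gene:
        if (
            evidence.tissue_expression_adequate is False
            or evidence.exon_expression_adequate is False
        ):
            return ReportDecision("excluded", 3, abstained)
        if (
            evidence.tissue_expression_adequate is None
            or evidence.exon_expression_adequate is None
        ):
            abstained.append("expression")

    # 4: novel gene, inadequate expression or pathway explicitly excluded
    if not evidence.known_disease_gene:
        if (
            evidence.tissue_expression_adequate is False
            or evidence.pathway_excluded is True
        ):
            return ReportDecision("excluded", 4, abstained)
        if (
            evidence.tissue_expression_adequate is None
            or evidence.pathway_excluded is None
        ):
            abstained.append("expression_or_pathway")

    # 5: predicted LoF curated as not LoF
    if v.is_plof:
        if evidence.lof_curation == "n/a":
            abstained.append("lof_curation")
        elif evidence.lof_curation in ("not_LoF", "likely_not_LoF"):
            return ReportDecision("excluded", 5, abstained)

    # 6: read-level artefact
    if evidence.igv_artefact is None:
        abstained.append("igv")
    elif evidence.igv_artefact:
        return ReportDecision("excluded", 6, abstained)

    return ReportDecision("reportable", None, abstained)


def reportable_count(
    candidate_sets: Iterable[CandidateSet],
    evidence: Mapping[tuple[str, int, str, str], EvidenceBundle],
) -> dict[str, int]:
    """Reportable verdicts per family.

    Evidence is keyed by site identity (chrom, pos, ref, alt).  A candidate
    with no evidence record is evaluated against an all-unknown bundle —
    every rule abstains and the candidate counts as reportable (flagged by
    its abstention list).
    """
    counts: dict[str, int] = {}
    for cs in candidate_sets:
        n = 0
        for cand in cs:
            bundle = evidence.get(cand.variant.key, EvidenceBundle())
            if evaluate_exclusions(cand, bundle).verdict == "reportable":
                n += 1
        counts[cs.family_id] = n
    return counts


# ---------------------------------------------------------------------------
# Evidence TSV
# ---------------------------------------------------------------------------

_BOOL = {"1": True, "0": False, "true": True, "false": False, "yes": True, "no": False}


def _parse_tristate(raw: str) -> Optional[bool]:
    raw = raw.strip().lower()
    if raw in ("", ".", "unknown", "na"):
        return None
    return _BOOL[raw]


def read_evidence(
    path: str | Path,
) -> dict[tuple[str, int, str, str], EvidenceBundle]:
    """Read an evidence TSV keyed by chrom/pos/ref/alt.

    Recognised columns (beyond the key): gene_disease_moi,
    second_hit_present, phenotype_match, tissue_expression_adequate,
    exon_expression_adequate, pathway_excluded, lof_curation, igv_artefact.
    Empty / ``.`` / ``unknown`` cells mean unknown.
    """
    out: dict[tuple[str, int, str, str], EvidenceBundle] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            out[key] = EvidenceBundle(
                gene_disease_moi=row.get("gene_disease_moi") or "none-known",
                second_hit_present=_parse_tristate(row.get("second_hit_present", "")),
                phenotype_match=_parse_tristate(row.get("phenotype_match", "")),
                tissue_expression_adequate=_parse_tristate(
                    row.get("tissue_expression_adequate", "")
                ),
                exon_expression_adequate=_parse_tristate(
                    row.get("exon_expression_adequate", "")
                ),
                pathway_excluded=_parse_tristate(row.get("pathway_excluded", "")),
                lof_curation=row.get("lof_curation") or "n/a",
                igv_artefact=_parse_tristate(row.get("igv_artefact", "")),
            )
    return out
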