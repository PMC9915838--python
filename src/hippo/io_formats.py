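"""Readers and writers for the standard formats the toolkit touches.

VCF access goes through :mod:`cyvcf2`; multi-allelic sites are split into
bi-allelic records on the way in, with per-allele depths and Number=A INFO
fields resolved by allele index.  Annotation ingestion supports two
dialects, both declared by an :class:`AnnotationSpec`:

* a VEP-CSQ-style packed INFO field (``Allele|SYMBOL|Consequence|...``);
* a sidecar TSV keyed by chrom/pos/ref/alt.

Missing annotations always map to *absent* (``None``), never to 0.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from cyvcf2 import VCF

from hippo.hippo_filter import CandidateSet
from hippo.records import (
    AnnotatedVariant,
    ClinVarStatus,
    GeneList,
    Genotype,
    MemberGenotype,
    Pedigree,
    PedigreeMember,
    TranscriptConsequence,
    Trio,
    TrioGenotypes,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

_PED_SEX = {"1": "male", "2": "female"}
_PED_AFFECTED = {"1": False, "2": True}


def read_pedigree(ped_path: str | Path) -> dict[str, Pedigree]:
    """Read a 6-column whitespace-delimited PED file.

    Columns: family, individual, father (0 = absent), mother (0 = absent),
    sex (1 = male, 2 = female, other = unknown), phenotype (1 = unaffected,
    2 = affected, other = unknown).  Returns one :class:`Pedigree` per
    family, validated for resolvable and acyclic parentage.
    """
    families: dict[str, Pedigree] = {}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected 6 columns, got {len(cols)}"
                )
            fam, iid, pat, mat, sex, pheno = cols[:6]
            ped = families.setdefault(fam, Pedigree(family_id=fam))
            ped.add(
                PedigreeMember(
                    individual_id=iid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_PED_SEX.get(sex),
                    affected=_PED_AFFECTED.get(pheno),
                )
            )
    for ped in families.values():
        ped.validate()
    return families


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

_GENCC_KEEP = {"strong", "definitive"}
_PANELAPP_KEEP = {"green"}
_HEADER_TOKENS = {"gene", "symbol", "gene_symbol", "genesymbol"}


def read_gene_list(
    tsv_path: str | Path,
    provenance: str = "custom",
    name: Optional[str] = None,
) -> GeneList:
    """Read a gene-list TSV: one symbol per row, optional classification
    column.

    For ``gencc_strong_definitive`` provenance only rows classified Strong
    or Definitive are kept; for ``panelapp_green`` only green-confidence
    rows.  Symbols are deduplicated; an empty resulting list is fatal.
    """
    keep = {
        "gencc_strong_definitive": _GENCC_KEEP,
        "panelapp_green": _PANELAPP_KEEP,
    }.get(provenance)
    symbols: set[str] = set()
    with open(tsv_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            symbol = cols[0].strip()
            if not symbol or symbol.lower() in _HEADER_TOKENS:
                continue
            if keep is not None:
                classification = cols[1].strip().lower() if len(cols) > 1 else ""
                if classification not in keep:
                    continue
            symbols.add(symbol)
    if not symbols:
        raise ValueError(f"{tsv_path}: gene list is empty after filtering")
    return GeneList(
        name=name or Path(tsv_path).stem,
        symbols=frozenset(symbols),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def _default_af_keys() -> dict[str, str]:
    return {
        "gnomad_exomes": "gnomADe_AF",
        "gnomad_genomes": "gnomADg_AF",
        "topmed": "TOPMED_AF",
        "exac": "ExAC_AF",
        "1000g": "KG_AF",
    }


@dataclass
class AnnotationSpec:
    """Declares where each consumed annotation lives in a VCF.

    ``csq_fields`` lists the ``|``-separated subfields of the packed
    consequence INFO field; when ``None`` the layout is parsed from the VCF
    header description (the VEP ``Format: ...`` convention).
    ``transcript_set`` declares which transcript annotation the consequences
    were computed on (RefSeq or Ensembl); it is carried as provenance, no
    default is asserted.
    """

    csq_key: str = "CSQ"
    csq_fields: Optional[list[str]] = None
    csq_allele_field: str = "Allele"
    csq_gene_field: str = "SYMBOL"
    csq_consequence_field: str = "Consequence"
    csq_transcript_field: str = "Feature"
    csq_distance_field: str = "EXON_DISTANCE"
    af_info_keys: dict[str, str] = field(default_factory=_default_af_keys)
    cohort_af_key: Optional[str] = "cohort_AF"
    cadd_key: Optional[str] = "CADD_PHRED"
    revel_key: Optional[str] = "REVEL"
    spliceai_key: Optional[str] = "SpliceAI_DS"
    clinvar_key: Optional[str] = "CLNSIG"
    exomiser_rank_key: Optional[str] = "ExomiserRank"
    exomiser_score_key: Optional[str] = "ExomiserScore"
    transcript_set: Optional[str] = None

    def resolve_csq_fields(self, vcf: VCF) -> Optional[list[str]]:
        if self.csq_fields is not None:
            return self.csq_fields
        try:
            desc = vcf.get_header_type(self.csq_key)["Description"]
        except KeyError:
            return None
        if "Format:" not in desc:
            return None
        layout = desc.split("Format:", 1)[1].strip().strip('"')
        return [f.strip() for f in layout.split("|")]


def _info_for_alt(value, alt_index: int):
    """Resolve a possibly Number=A INFO value for one alt allele."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        v = value[alt_index] if alt_index < len(value) else None
        return v
    return value


def _as_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if f != f else f  # NaN encodes missing in cyvcf2 arrays


def _member_genotype(
    gt_row: Sequence[int],
    ad_row,
    gq,
    alt_allele_number: int,
) -> MemberGenotype:
    alleles = [a for a in gt_row[:-1] if isinstance(a, int)]
    known = [a for a in alleles if a >= 0]
    if not known:
        genotype = Genotype.MISSING
    else:
        count = sum(1 for a in known if a == alt_allele_number)
        if len(known) == 1:
            genotype = Genotype.HEMI if count == 1 else Genotype.HOM_REF
        else:
            genotype = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[count]
    ref_reads = alt_reads = 0
    if ad_row is not None:
        vals = list(ad_row)
        if vals and vals[0] >= 0:
            ref_reads = int(vals[0])
        if alt_allele_number < len(vals) and vals[alt_allele_number] >= 0:
            alt_reads = int(vals[alt_allele_number])
    gq_val = None
    if gq is not None:
        g = _as_float(gq)
        if g is not None and g >= 0:
            gq_val = int(g)
    return MemberGenotype(
        genotype=genotype, ref_reads=ref_reads, alt_reads=alt_reads, gq=gq_val
    )


def _parse_csq(
    raw: str,
    fields: list[str],
    spec: AnnotationSpec,
    alt: str,
    n_alts: int,
) -> list[TranscriptConsequence]:
    idx = {name: i for i, name in enumerate(fields)}
    out: list[TranscriptConsequence] = []
    for entry in str(raw).split(","):
        parts = entry.split("|")

        def get(field_name: str) -> str:
            i = idx.get(field_name)
            return parts[i].strip() if i is not None and i < len(parts) else ""

        if n_alts > 1 and spec.csq_allele_field in idx:
            if get(spec.csq_allele_field) != alt:
                continue
        terms = get(spec.csq_consequence_field)
        if not terms:
            continue
        transcript = get(spec.csq_transcript_field) or "unknown"
        gene = get(spec.csq_gene_field) or None
        dist_raw = get(spec.csq_distance_field)
        distance = int(dist_raw) if dist_raw not in ("", ".") else None
        for term in terms.split("&"):
            out.append(
                TranscriptConsequence(
                    transcript_id=transcript,
                    term=term,
                    distance_to_exon=distance,
                    gene=gene,
                )
            )
    return out


def read_trio_vcf(
    vcf_path: str | Path,
    trio: Trio,
    spec: Optional[AnnotationSpec] = None,
    sidecar: Optional[dict[tuple[str, int, str, str], dict]] = None,
) -> Iterator[tuple[AnnotatedVariant, TrioGenotypes]]:
    """Stream normalised (variant, genotypes) records for one analysis trio.

    Multi-allelic sites are split into one bi-allelic record per alt allele,
    with per-allele depths and Number=A annotations resolved by index.
    Records are yielded in the file's coordinate order.  A pedigree sample
    missing from the VCF is fatal; absent parents (duo support) are simply
    ``None`` in the emitted :class:`TrioGenotypes`.

    ``sidecar`` (as returned by :func:`read_sidecar_annotations`) supplies or
    overrides annotations for matching sites.
    """
    spec = spec or AnnotationSpec()
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    roles: dict[str, Optional[int]] = {}
    for role, sid in (
        ("proband", trio.proband_id),
        ("mother", trio.mother_id),
        ("father", trio.father_id),
    ):
        if sid is None:
            roles[role] = None
        elif sid not in samples:
            raise ValueError(
                f"{vcf_path}: sample {sid!r} ({role}) not in VCF samples {samples}"
            )
        else:
            roles[role] = samples.index(sid)
    if roles["proband"] is None:
        raise ValueError("trio has no proband sample")

    csq_fields = spec.resolve_csq_fields(vcf)

    for record in vcf:
        n_alts = len(record.ALT)
        ad = record.format("AD")
        gq = record.gt_quals
        for alt_index, alt in enumerate(record.ALT):
            if alt in ("*", "<NON_REF>"):
                continue
            alt_number = alt_index + 1

            def info(key: Optional[str]):
                if key is None:
                    return None
                return _info_for_alt(record.INFO.get(key), alt_index)

            consequences: list[TranscriptConsequence] = []
            if csq_fields is not None:
                raw_csq = record.INFO.get(spec.csq_key)
                if raw_csq is not None:
                    try:
                        consequences = _parse_csq(
                            raw_csq, csq_fields, spec, alt, n_alts
                        )
                    except (IndexError, ValueError) as exc:
                        raise ValueError(
                            f"{vcf_path}: unparseable {spec.csq_key} at "
                            f"{record.CHROM}:{record.POS}: {exc}"
                        ) from exc

            af_sources = {}
            for source, key in spec.af_info_keys.items():
                val = _as_float(info(key))
                if val is not None:
                    af_sources[source] = val

            rank = info(spec.exomiser_rank_key)
            variant = AnnotatedVariant(
                chrom=record.CHROM,
                pos=record.POS,
                ref=record.REF,
                alt=alt,
                gene=next((c.gene for c in consequences if c.gene), None),
                consequences=consequences,
                af_sources=af_sources,
                cohort_af=_as_float(info(spec.cohort_af_key)),
                cadd=_as_float(info(spec.cadd_key)),
                revel=_as_float(info(spec.revel_key)),
                spliceai=_as_float(info(spec.spliceai_key)),
                clinvar=ClinVarStatus.parse(info(spec.clinvar_key)),
                exomiser_rank=int(rank) if rank is not None else None,
                exomiser_score=_as_float(info(spec.exomiser_score_key)),
                filter_status=record.FILTER or "PASS",
            )
            if sidecar:
                row = sidecar.get(variant.key)
                if row:
                    _apply_sidecar_row(variant, row)

            members = {}
            for role, sample_index in roles.items():
                if sample_index is None:
                    members[role] = None
                    continue
                members[role] = _member_genotype(
                    record.genotypes[sample_index],
                    ad[sample_index] if ad is not None else None,
                    gq[sample_index] if gq is not None else None,
                    alt_number,
                )
            yield variant, TrioGenotypes(**members)


# ---------------------------------------------------------------------------
# Sidecar annotation TSV
# ---------------------------------------------------------------------------

_SIDECAR_FLOATS = {"cohort_af", "cadd", "revel", "spliceai", "exomiser_score"}


def read_sidecar_annotations(
    tsv_path: str | Path,
) -> dict[tuple[str, int, str, str], dict]:
    """Read a sidecar annotation TSV keyed by chrom/pos/ref/alt.

    Recognised columns: ``gene``, ``transcript``, ``consequence``,
    ``distance_to_exon``, any number of ``af_<source>`` columns,
    ``cohort_af``, ``cadd``, ``revel``, ``spliceai``, ``clinvar``,
    ``exomiser_rank``, ``exomiser_score``.  Empty cells mean absent.
    """
    out: dict[tuple[str, int, str, str], dict] = {}
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            out[key] = {
                k: v for k, v in row.items() if v not in ("", ".", None)
            }
    return out


def _apply_sidecar_row(variant: AnnotatedVariant, row: dict) -> None:
    for col, raw in row.items():
        if col in ("chrom", "pos", "ref", "alt"):
            continue
        if col.startswith("af_"):
            variant.af_sources[col[3:]] = float(raw)
        elif col in _SIDECAR_FLOATS:
            setattr(variant, col, float(raw))
        elif col == "exomiser_rank":
            variant.exomiser_rank = int(raw)
        elif col == "clinvar":
            variant.clinvar = ClinVarStatus.parse(raw)
        elif col == "gene":
            variant.gene = raw
        elif col == "consequence":
            dist = row.get("distance_to_exon")
            variant.consequences.append(
                TranscriptConsequence(
                    transcript_id=row.get("transcript", "sidecar"),
                    term=raw,
                    distance_to_exon=int(dist) if dist not in (None, "", ".") else None,
                    gene=row.get("gene"),
                )
            )


# ---------------------------------------------------------------------------
# Candidate TSV
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "family",
    "strategy",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "gnomad_af",
    "cadd",
    "revel",
    "clinvar",
    "inheritance",
    "proband_genotype",
    "mode",
    "comp_het_partner",
    "rule_trail",
]


def write_candidate_sets(
    candidate_sets: Sequence[CandidateSet], tsv_path: str | Path
) -> None:
    """Write one or more candidate sets as a TSV with a deterministic column
    order.

    An empty input produces a header-only file.  The written columns
    round-trip through :func:`read_candidates` losslessly.
    """
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for cs in candidate_sets:
            for cand in cs:
                v = cand.variant
                best = v.consequences[0].canonical if v.consequences else ""
                proband = cand.trio.proband if cand.trio is not None else None
                writer.writerow(
                    [
                        cs.family_id,
                        cs.strategy,
                        v.chrom,
                        v.pos,
                        v.ref,
                        v.alt,
                        v.gene or "",
                        best,
                        f"{v.max_af:g}",
                        "" if v.cadd is None else f"{v.cadd:g}",
                        "" if v.revel is None else f"{v.revel:g}",
                        v.clinvar.value,
                        cand.label.value,
                        proband.genotype.value if proband is not None else "",
                        cand.mode,
                        (
                            ":".join(map(str, cand.comp_het_partner))
                            if cand.comp_het_partner
                            else ""
                        ),
                        ";".join(cand.trail),
                    ]
                )


def write_candidates(candidate_set: CandidateSet, tsv_path: str | Path) -> None:
    """Write a single candidate set (see :func:`write_candidate_sets`)."""
    write_candidate_sets([candidate_set], tsv_path)


def read_candidates(tsv_path: str | Path) -> list[dict]:
    """Read a candidates TSV back as a list of row dicts (column order and
    values exactly as written)."""
    with open(tsv_path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
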