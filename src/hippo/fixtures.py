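"""Packaged study tables: the transcribed cohort, count and report fixtures.

Four small TSVs ship with the package (under ``hippo/data``):

* ``cohort_families.tsv`` — the 9 family structures (8 trios and a quad);
* ``comparison_counts.tsv`` — per-family variants passing each strategy's
  filtering, plus the GenCC-restricted subset and comparability flags;
* ``reported_variants.tsv`` — the 17 variants reported by the research exome
  arm with their printed annotations;
* ``gms_reported_variants.tsv`` — the 5 variants on the clinical genome
  reports.

Each file is checksummed at load time; a mismatch is fatal (the tables are
reference data, not inputs to be edited in place).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from typing import Optional

import pandas as pd

from hippo.metrics import ReportedVariant
from hippo.records import AnnotatedVariant, ClinVarStatus, TranscriptConsequence

_FIXTURE_FILES = {
    "families": "cohort_families.tsv",
    "comparison": "comparison_counts.tsv",
    "reported_variants": "reported_variants.tsv",
    "gms_reported": "gms_reported_variants.tsv",
}


def _data_bytes(filename: str) -> bytes:
    return resources.files("hippo.data").joinpath(filename).read_bytes()


def _verify_checksums() -> None:
    expected = json.loads(_data_bytes("checksums.json"))
    for filename, digest in expected.items():
        actual = hashlib.sha256(_data_bytes(filename)).hexdigest()
        if actual != digest:
            raise RuntimeError(
                f"packaged fixture {filename} is corrupted "
                f"(sha256 {actual} != {digest})"
            )


def study_tables(verify: bool = True) -> dict[str, pd.DataFrame]:
    """Load the packaged study tables as DataFrames, verifying checksums."""
    if verify:
        _verify_checksums()
    out = {}
    for key, filename in _FIXTURE_FILES.items():
        with resources.files("hippo.data").joinpath(filename).open() as fh:
            out[key] = pd.read_csv(fh, sep="\t", comment="#")
    return out


def _opt_float(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def reported_variant_records(
    tables: Optional[dict[str, pd.DataFrame]] = None,
) -> list[tuple[AnnotatedVariant, str]]:
    """The 17 reported exome variants as annotated records, each with its
    inheritance search mode (dominant / recessive).

    Used to re-run the HiPPo retention rules over the printed annotations.
    The per-variant depths and genotype qualities were not published, so the
    records are annotation-only.
    """
    tables = tables or study_tables()
    df = tables["reported_variants"]
    out = []
    for row in df.itertuples(index=False):
        transcript = str(row.hgvsc).split(":", 1)[0] if pd.notna(row.hgvsc) else "na"
        af = float(row.gnomad_af)
        variant = AnnotatedVariant(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            consequences=[
                TranscriptConsequence(
                    transcript_id=transcript,
                    term=row.consequence,
                    distance_to_exon=0,
                    gene=row.gene,
                )
            ],
            af_sources={"gnomad_exomes": af} if af > 0 else {},
            cadd=_opt_float(row.cadd),
            revel=_opt_float(row.revel),
            clinvar=ClinVarStatus.parse(
                None if pd.isna(row.clinvar) else row.clinvar
            ),
        )
        out.append((variant, row.mode))
    return out


def hippo_reported_variants(
    tables: Optional[dict[str, pd.DataFrame]] = None,
) -> list[ReportedVariant]:
    """The exome arm's reported set with diagnostic flags."""
    tables = tables or study_tables()
    df = tables["reported_variants"]
    return [
        ReportedVariant(
            family=row.family,
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            classification=row.acmg,
            diagnostic=bool(row.diagnostic),
        )
        for row in df.itertuples(index=False)
    ]


def gms_reported_variants(
    tables: Optional[dict[str, pd.DataFrame]] = None,
) -> list[ReportedVariant]:
    """The clinical genome arm's reported set with diagnostic flags."""
    tables = tables or study_tables()
    df = tables["gms_reported"]
    return [
        ReportedVariant(
            family=row.family,
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            classification=row.classification,
            diagnostic=bool(row.diagnostic),
        )
        for row in df.itertuples(index=False)
    ]


def comparison_inputs(
    tables: Optional[dict[str, pd.DataFrame]] = None,
) -> dict:
    """Assemble :func:`hippo.metrics.compare_strategies` inputs from the
    packaged tables: per-family assessed counts for each arm, the
    GenCC-restricted counts, reported sets, and the incomparable-family set
    (trio structures differing between arms)."""
    tables = tables or study_tables()
    df = tables["comparison"]
    hippo_assessed = {r.family: int(r.hippo_n) for r in df.itertuples(index=False)}
    gencc_assessed = {r.family: int(r.gencc_n) for r in df.itertuples(index=False)}
    gms_assessed = {
        r.family: (None if pd.isna(r.gms_n) else int(r.gms_n))
        for r in df.itertuples(index=False)
    }
    incomparable = {
        r.family
        for r in df.itertuples(index=False)
        if not r.comparable and not pd.isna(r.gms_n)
    }
    return {
        "hippo_assessed": hippo_assessed,
        "gms_assessed": gms_assessed,
        "gencc_assessed": gencc_assessed,
        "hippo_reported": hippo_reported_variants(tables),
        "gms_reported": gms_reported_variants(tables),
        "incomparable": incomparable,
    }
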