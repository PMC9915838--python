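"""Shared fixtures: record factories, a small simulated cohort, study tables."""

from __future__ import annotations

import csv
from typing import Optional

import pytest

from hippo import fixtures as study_fix
from hippo.records import (
    AnnotatedVariant,
    ClinVarStatus,
    Genotype,
    MemberGenotype,
    TranscriptConsequence,
    TrioGenotypes,
)
from hippo.synthetic_cohort import SimulationConfig, generate_cohort


def make_variant(
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    gene: str = "GENE1",
    consequence: str = "missense",
    distance: Optional[int] = 0,
    af: Optional[float] = None,
    cohort_af: Optional[float] = None,
    cadd: Optional[float] = None,
    revel: Optional[float] = None,
    spliceai: Optional[float] = None,
    clinvar: str = "absent",
    exomiser_rank: Optional[int] = None,
    exomiser_score: Optional[float] = None,
    filter_status: str = "PASS",
) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequences=[
            TranscriptConsequence(
                transcript_id="tx1",
                term=consequence,
                distance_to_exon=distance,
                gene=gene,
            )
        ],
        af_sources={} if af is None else {"gnomad_exomes": af},
        cohort_af=cohort_af,
        cadd=cadd,
        revel=revel,
        spliceai=spliceai,
        clinvar=ClinVarStatus.parse(clinvar),
        exomiser_rank=exomiser_rank,
        exomiser_score=exomiser_score,
        filter_status=filter_status,
    )


def gt(code: str, ref_reads: int = 15, alt_reads: int = 15, gq: int = 60) -> MemberGenotype:
    return MemberGenotype(
        genotype=Genotype(code), ref_reads=ref_reads, alt_reads=alt_reads, gq=gq
    )


def make_trio(
    proband: str = "het",
    mother: Optional[str] = "hom_ref",
    father: Optional[str] = "hom_ref",
    proband_gq: int = 60,
    proband_ab: tuple[int, int] = (15, 15),
) -> TrioGenotypes:
    def member(code, is_proband=False):
        if code is None:
            return None
        if is_proband:
            return gt(code, *proband_ab, gq=proband_gq)
        reads = (30, 0) if code == "hom_ref" else (15, 15)
        return gt(code, *reads)

    return TrioGenotypes(
        proband=member(proband, True),
        mother=member(mother),
        father=member(father),
    )


@pytest.fixture(scope="session")
def study_tables_fixture():
    return study_fix.study_tables()


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """A two-family simulated cohort with its truth table parsed."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SimulationConfig(seed=7, n_families=2)
    paths = generate_cohort(cfg, out)
    truth = {}
    with open(paths.truth) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["family"], row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            truth[key] = row
    return cfg, paths, truth
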