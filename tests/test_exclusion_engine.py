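"""Reporting exclusion criteria: firing conditions, precedence, abstention."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippo.exclusion_engine import (
    EvidenceBundle,
    ReportDecision,
    evaluate_exclusions,
    expression_adequate,
    reportable_count,
)
from hippo.hippo_filter import Candidate, CandidateSet
from hippo.inheritance import InheritanceLabel

from conftest import make_trio, make_variant


def cand(variant=None, label=InheritanceLabel.DE_NOVO, comp_het=False, proband="het"):
    return Candidate(
        variant=variant or make_variant(),
        label=label,
        mode="dominant",
        trail=["pass:all"],
        trio=make_trio(proband),
        comp_het_partner=("1", 999, "A", "T") if comp_het else None,
    )


class TestCriteria:
    def test_lone_het_in_recessive_gene_without_second_hit_excluded(self):
        evidence = EvidenceBundle(gene_disease_moi="AR", second_hit_present=False)
        d = evaluate_exclusions(cand(label=InheritanceLabel.INHERITED_HET_MAT), evidence)
        assert (d.verdict, d.criterion) == ("excluded", 1)

    def test_comp_het_partner_escapes_criterion_1(self):
        evidence = EvidenceBundle(gene_disease_moi="AR", second_hit_present=False)
        d = evaluate_exclusions(cand(comp_het=True), evidence)
        assert d.verdict == "reportable"

    def test_phenotype_mismatch_in_known_gene_excluded(self):
        evidence = EvidenceBundle(gene_disease_moi="AD", phenotype_match=False)
        d = evaluate_exclusions(cand(), evidence)
        assert (d.verdict, d.criterion) == ("excluded", 2)

    def test_clinvar_pathogenic_immune_to_phenotype_mismatch(self):
        v = make_variant(clinvar="P")
        evidence = EvidenceBundle(gene_disease_moi="AD", phenotype_match=False)
        assert evaluate_exclusions(cand(v), evidence).verdict == "reportable"

    def test_poor_expression_in_known_gene_excluded(self):
        for field in ("tissue_expression_adequate", "exon_expression_adequate"):
            evidence = EvidenceBundle(gene_disease_moi="AD", **{field: False})
            d = evaluate_exclusions(cand(), evidence)
            assert (d.verdict, d.criterion) == ("excluded", 3)

    def test_novel_gene_expression_or_pathway_excluded(self):
        d1 = evaluate_exclusions(
            cand(), EvidenceBundle(tissue_expression_adequate=False)
        )
        d2 = evaluate_exclusions(cand(), EvidenceBundle(pathway_excluded=True))
        assert (d1.verdict, d1.criterion) == ("excluded", 4)
        assert (d2.verdict, d2.criterion) == ("excluded", 4)

    def test_novel_gene_de_novo_with_supportive_evidence_reportable(self):
        # the new-disease-gene profile: expression adequate, pathway plausible
        v = make_variant(chrom="13", pos=30462666, ref="CT", alt="C",
                         gene="HMGB1", consequence="frameshift")
        evidence = EvidenceBundle(
            tissue_expression_adequate=True,
            pathway_excluded=False,
            lof_curation="LoF",
            igv_artefact=False,
        )
        assert evaluate_exclusions(cand(v), evidence).verdict == "reportable"

    def test_curated_not_lof_excluded(self):
        v = make_variant(consequence="stop_gained")
        for curation in ("not_LoF", "likely_not_LoF"):
            evidence = EvidenceBundle(lof_curation=curation)
            d = evaluate_exclusions(cand(v), evidence)
            assert (d.verdict, d.criterion) == ("excluded", 5)

    def test_lof_curation_ignored_for_non_lof_variants(self):
        evidence = EvidenceBundle(lof_curation="not_LoF")
        assert evaluate_exclusions(cand(make_variant()), evidence).verdict == "reportable"

    def test_igv_artefact_excluded(self):
        d = evaluate_exclusions(cand(), EvidenceBundle(igv_artefact=True))
        assert (d.verdict, d.criterion) == ("excluded", 6)

    def test_lowest_criterion_wins(self):
        evidence = EvidenceBundle(
            gene_disease_moi="AR",
            second_hit_present=False,
            phenotype_match=False,
            igv_artefact=True,
        )
        d = evaluate_exclusions(cand(label=InheritanceLabel.INHERITED_HET_MAT), evidence)
        assert d.criterion == 1

    def test_all_unknown_abstains_everywhere_and_reports(self):
        d = evaluate_exclusions(cand(make_variant(consequence="stop_gained")),
                                EvidenceBundle())
        assert d.verdict == "reportable"
        assert "igv" in d.abstained and "lof_curation" in d.abstained


_tristate = st.sampled_from([None, True, False])


def _bundles():
    return st.builds(
        EvidenceBundle,
        gene_disease_moi=st.sampled_from(["AD", "AR", "XL", "none-known"]),
        second_hit_present=_tristate,
        phenotype_match=_tristate,
        tissue_expression_adequate=_tristate,
        exon_expression_adequate=_tristate,
        pathway_excluded=_tristate,
        lof_curation=st.sampled_from(
            ["LoF", "likely_LoF", "not_LoF", "likely_not_LoF", "n/a"]
        ),
        igv_artefact=_tristate,
    )


@settings(max_examples=200, derandomize=True)
@given(bundle=_bundles(), data=st.data())
def test_adding_evidence_is_monotone_toward_exclusion(bundle, data):
    """Resolving an unknown field never flips an excluded verdict back to
    reportable, and every excluded verdict carries exactly one criterion."""
    candidate = cand(
        make_variant(consequence=data.draw(st.sampled_from(["missense", "stop_gained"])))
    )
    before = evaluate_exclusions(candidate, bundle)
    if before.verdict == "excluded":
        assert before.criterion in range(1, 7)

    unknown_fields = [
        f.name
        for f in dataclasses.fields(bundle)
        if getattr(bundle, f.name) is None
    ]
    if not unknown_fields:
        return
    field = data.draw(st.sampled_from(unknown_fields))
    value = data.draw(st.booleans())
    after = evaluate_exclusions(
        candidate, dataclasses.replace(bundle, **{field: value})
    )
    if before.verdict == "excluded":
        assert after.verdict == "excluded"


def test_reportable_counts_per_family():
    v1, v2 = make_variant(pos=1000), make_variant(pos=2000, consequence="stop_gained")
    cs = CandidateSet(family_id="FAM_A", strategy="hippo",
                      candidates=[cand(v1), cand(v2)])
    # no evidence: everything abstains, everything counts
    assert reportable_count([cs], {}) == {"FAM_A": 2}
    # both artefactual: nothing reportable
    artefact = {v.key: EvidenceBundle(igv_artefact=True) for v in (v1, v2)}
    assert reportable_count([cs], artefact) == {"FAM_A": 0}


def test_expression_adequacy_thresholds_and_unknowns():
    assert expression_adequate(tpm=5.0, pext=0.8) == (True, True)
    assert expression_adequate(tpm=0.2, pext=0.05) == (False, False)
    # inclusive at the default cut-offs; missing values stay unknown
    assert expression_adequate(tpm=1.0) == (True, None)
    assert expression_adequate(pext=0.1) == (None, True)
    assert expression_adequate() == (None, None)


def test_report_decision_invariants():
    with pytest.raises(ValueError):
        ReportDecision("excluded", None)
    with pytest.raises(ValueError):
        ReportDecision("reportable", 3)
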