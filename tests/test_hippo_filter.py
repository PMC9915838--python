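"""HiPPo retention rules: worked examples, overrides, monotonicity."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippo.config import FilterConfig
from hippo.hippo_filter import (
    Candidate,
    CandidateSet,
    clinvar_override,
    hippo_retain,
    restrict_to_genes,
    run_hippo,
)
from hippo.inheritance import InheritanceLabel
from hippo.records import GeneList, Trio

from conftest import make_trio, make_variant

DN = InheritanceLabel.DE_NOVO
HET_MAT = InheritanceLabel.INHERITED_HET_MAT


class TestWorkedExamples:
    def test_de_novo_missense_rare_high_cadd_retained(self):
        # the canonical confirmed-diagnosis profile: novel, damaging, de novo
        v = make_variant(chrom="2", pos=28776944, ref="C", alt="G",
                         gene="PPP1CB", cadd=26.7, revel=0.438, clinvar="P")
        retained, trail = hippo_retain(v, make_trio("het"), DN)
        assert retained

    def test_common_missense_removed_by_af_rule(self):
        v = make_variant(af=0.01, cadd=30)
        retained, trail = hippo_retain(v, make_trio("het"), HET_MAT)
        assert not retained
        assert any(t.startswith("fail:af") for t in trail)

    def test_low_cadd_removed(self):
        v = make_variant(cadd=12)
        retained, trail = hippo_retain(v, make_trio("het"), DN)
        assert not retained
        assert any(t.startswith("fail:cadd") for t in trail)

    def test_recessive_mode_admits_higher_af(self):
        # comp-het partner profile: AF above the dominant ceiling, below the
        # recessive one
        v = make_variant(chrom="7", pos=1480876, gene="INTS1", af=5.56e-4, cadd=23.5)
        retained, _ = hippo_retain(v, make_trio("het"), HET_MAT, mode="recessive")
        assert retained
        # the recessive ceiling is 0.05: AF 0.01 passes it (unlike dominant)
        # but AF 0.06 fails both
        mid = make_variant(af=0.01, cadd=23.5)
        assert not hippo_retain(mid, make_trio("het"), HET_MAT, mode="dominant")[0]
        assert hippo_retain(mid, make_trio("het"), HET_MAT, mode="recessive")[0]
        common = make_variant(af=0.06, cadd=23.5)
        assert not hippo_retain(common, make_trio("het"), HET_MAT, mode="recessive")[0]

    def test_cohort_af_rule(self):
        v = make_variant(af=1e-5, cadd=25, cohort_af=0.02)
        assert not hippo_retain(v, make_trio("het"), DN)[0]

    def test_synonymous_excluded_even_with_high_spliceai(self):
        v = make_variant(consequence="synonymous", spliceai=0.9, cadd=20)
        retained, trail = hippo_retain(v, make_trio("het"), DN)
        assert not retained
        assert "fail:consequence" in trail

    def test_intronic_within_window_needs_spliceai(self):
        near = dict(consequence="intron", distance=15, cadd=20)
        supported = make_variant(spliceai=0.5, **near)
        unsupported = make_variant(spliceai=0.05, **near)
        assert hippo_retain(supported, make_trio("het"), DN)[0]
        assert not hippo_retain(unsupported, make_trio("het"), DN)[0]

    def test_intronic_outside_window_removed(self):
        v = make_variant(consequence="intron", distance=25, spliceai=0.9, cadd=20)
        assert not hippo_retain(v, make_trio("het"), DN)[0]

    def test_canonical_splice_without_spliceai_retained_as_plof(self):
        v = make_variant(consequence="splice_donor", distance=None, cadd=30)
        retained, trail = hippo_retain(v, make_trio("het"), DN)
        assert retained
        assert "note:canonical_splice_spliceai_absent" in trail

    def test_absent_cadd_is_not_zero_cadd(self):
        absent = make_variant(cadd=None)
        zero = make_variant(cadd=0.0)
        ok_absent, trail_absent = hippo_retain(absent, make_trio("het"), DN)
        ok_zero, trail_zero = hippo_retain(zero, make_trio("het"), DN)
        assert ok_absent and "note:cadd_absent" in trail_absent
        assert not ok_zero

    def test_allele_balance_boundary_fails_strictly(self):
        v = make_variant(cadd=25)
        at_boundary = make_trio("het", proband_ab=(8, 2))  # balance exactly 0.2
        above = make_trio("het", proband_ab=(7, 3))
        assert not hippo_retain(v, at_boundary, DN)[0]
        assert hippo_retain(v, above, DN)[0]

    def test_gq_boundary_fails_strictly(self):
        v = make_variant(cadd=25)
        assert not hippo_retain(v, make_trio("het", proband_gq=40), DN)[0]
        assert hippo_retain(v, make_trio("het", proband_gq=41), DN)[0]

    def test_annotation_only_records_skip_genotype_rules(self):
        v = make_variant(cadd=25)
        retained, trail = hippo_retain(v, None, InheritanceLabel.UNINFORMATIVE)
        assert retained
        assert "note:genotype_rules_skipped" in trail


class TestClinvarOverride:
    def test_pathogenic_inherited_from_unaffected_parent_retained(self):
        # off-panel pathogenic stop-gain carried by an unaffected parent
        v = make_variant(chrom="11", pos=17413408, gene="ABCC8",
                         consequence="stop_gained", cadd=43, clinvar="P")
        retained, trail = hippo_retain(v, make_trio("het", father="het"), HET_MAT)
        assert retained
        assert "pass:clinvar_override_plp" in trail

    def test_override_rescues_low_cadd(self):
        v = make_variant(cadd=5, clinvar="LP")
        assert hippo_retain(v, make_trio("het"), HET_MAT)[0]

    def test_benign_with_high_cadd_removed(self):
        v = make_variant(cadd=30, clinvar="B")
        retained, trail = hippo_retain(v, make_trio("het"), DN)
        assert not retained
        assert clinvar_override(v) is False

    def test_vus_gets_normal_rules(self):
        assert not hippo_retain(make_variant(cadd=10, clinvar="VUS"), make_trio("het"), DN)[0]
        assert hippo_retain(make_variant(cadd=20, clinvar="VUS"), make_trio("het"), DN)[0]

    def test_af_safety_ceiling_blocks_override(self):
        v = make_variant(af=0.1, clinvar="P", cadd=30)
        retained, trail = hippo_retain(v, make_trio("het"), HET_MAT)
        assert not retained
        assert "note:clinvar_override_blocked_by_af_ceiling" in trail

    @settings(max_examples=50, derandomize=True)
    @given(
        cadd_min=st.floats(0, 60),
        af_max=st.floats(1e-6, 0.001),
        gq_min=st.integers(0, 99),
    )
    def test_override_dominates_every_threshold_configuration(
        self, cadd_min, af_max, gq_min
    ):
        cfg = FilterConfig.hippo().with_overrides(
            cadd_min=cadd_min, af_max_dominant=af_max, gq_min=gq_min
        )
        v = make_variant(af=af_max / 2, cadd=1.0, clinvar="P")
        assert hippo_retain(v, make_trio("het", proband_gq=1), DN, cfg)[0]


# -- monotonicity -----------------------------------------------------------


def _variant_pool():
    """A deterministic spread of annotation profiles around every threshold."""
    pool = []
    i = 0
    for af in (0.0, 1e-5, 5e-4, 2e-3, 0.02, 0.2):
        for cadd in (None, 5.0, 14.9, 15.1, 30.0):
            for clinvar in ("absent", "P", "B", "VUS"):
                i += 1
                pool.append(
                    make_variant(
                        pos=1000 + i,
                        af=af if af else None,
                        cadd=cadd,
                        clinvar=clinvar,
                        gene=f"G{i % 7}",
                    )
                )
    return pool


def _retained_keys(cfg):
    return {
        v.key
        for v in _variant_pool()
        if hippo_retain(v, make_trio("het"), HET_MAT, cfg)[0]
    }


@pytest.mark.parametrize(
    "tighten",
    [
        {"cadd_min": 25.0},
        {"af_max_dominant": 1e-4},
        {"cohort_af_max": 1e-3},
        {"gq_min": 80},
    ],
    ids=lambda d: next(iter(d)),
)
def test_tightening_any_threshold_never_grows_the_retained_set(tighten):
    base = FilterConfig.hippo()
    assert _retained_keys(base.with_overrides(**tighten)) <= _retained_keys(base)


def test_restrict_to_genes_is_always_a_subset():
    trio = Trio(family_id="F", proband_id="p")
    cs = run_hippo(
        [(v, make_trio("het")) for v in _variant_pool()], trio
    )
    everything = GeneList("all", frozenset(cs.genes() or {"X"}))
    nothing_shared = GeneList("other", frozenset({"NOT_A_GENE"}))
    some = GeneList("some", frozenset({"G1", "G3"}))
    assert restrict_to_genes(cs, everything).keys() == cs.keys()
    assert len(restrict_to_genes(cs, nothing_shared)) == 0
    assert restrict_to_genes(cs, some).keys() <= cs.keys()


def test_candidate_sets_reject_empty_rule_trails():
    v = make_variant()
    with pytest.raises(ValueError):
        CandidateSet(
            family_id="F",
            strategy="hippo",
            candidates=[Candidate(variant=v, label=DN, mode="dominant", trail=[])],
        )
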