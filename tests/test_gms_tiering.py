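"""GMS panel tiering: prefilter, tier assignment, Tier A and panel monotonicity."""

from __future__ import annotations

import pytest

from hippo.config import FilterConfig
from hippo.gms_tiering import (
    CnvRecord,
    GenomicIntervals,
    Tier,
    assign_tier,
    gene_agnostic_flags,
    gms_prefilter,
    run_gms,
    tier_a_cnv,
)
from hippo.hippo_filter import run_hippo
from hippo.inheritance import InheritanceLabel
from hippo.records import GeneList, Trio

from conftest import make_trio, make_variant

DN = InheritanceLabel.DE_NOVO
HET_MAT = InheritanceLabel.INHERITED_HET_MAT

R29 = GeneList("R29", frozenset({"CHAMP1", "PPP1CB", "INTS1"}), "panelapp_green")


class TestPrefilter:
    def test_rare_inherited_missense_passes_recessive_mode(self):
        v = make_variant(af=5e-4, gene="INTS1")
        assert gms_prefilter(v, make_trio("het"), HET_MAT, mode="recessive")

    def test_dominant_af_ceiling_is_tighter(self):
        v = make_variant(af=5e-3)
        assert not gms_prefilter(v, make_trio("het"), HET_MAT, mode="dominant")
        assert gms_prefilter(v, make_trio("het"), HET_MAT, mode="recessive")

    def test_intronic_outside_8bp_window_fails(self):
        # HiPPo's 20 bp window would keep this; the panel strategy does not
        v = make_variant(consequence="intron", distance=15, spliceai=0.8)
        assert not gms_prefilter(v, make_trio("het"), DN)
        assert v.qualifying_consequences(20)

    def test_non_pass_de_novo_coding_bypasses_quality_rules(self):
        v = make_variant(filter_status="LowQual")
        assert gms_prefilter(v, make_trio("het", proband_gq=10), DN)
        # the same variant inherited has no bypass
        assert not gms_prefilter(v, make_trio("het"), HET_MAT)

    def test_gq_boundary_strict(self):
        v = make_variant()
        assert not gms_prefilter(v, make_trio("het", proband_gq=30), HET_MAT)
        assert gms_prefilter(v, make_trio("het", proband_gq=31), HET_MAT)


class TestAssignTier:
    def test_de_novo_stop_gain_on_panel_is_tier1(self):
        v = make_variant(chrom="13", pos=114325034, ref="C", alt="T",
                         gene="CHAMP1", consequence="stop_gained")
        a = assign_tier(v, DN, [R29])
        assert a.tier is Tier.TIER1
        assert a.panel == "R29"

    def test_off_panel_inherited_plof_is_untiered(self):
        # pathogenic stop-gain missed because its gene is absent from the
        # applied panel and it is neither de novo nor Exomiser-ranked
        v = make_variant(gene="ABCC8", consequence="stop_gained")
        assert assign_tier(v, HET_MAT, [R29]).tier is Tier.UNTIERED

    def test_off_panel_low_exomiser_rank_is_untiered(self):
        v = make_variant(gene="PKD1L3", exomiser_rank=33, exomiser_score=0.7)
        assert assign_tier(v, HET_MAT, [R29]).tier is Tier.UNTIERED

    def test_off_panel_top_exomiser_hit_is_gene_agnostic(self):
        v = make_variant(gene="XYZ", exomiser_rank=2, exomiser_score=0.97)
        assert assign_tier(v, HET_MAT, [R29]).tier is Tier.GENE_AGNOSTIC_EXOMISER

    def test_exomiser_thresholds_inclusive_score_top3_rank(self):
        ok = make_variant(exomiser_rank=3, exomiser_score=0.95)
        rank_out = make_variant(exomiser_rank=4, exomiser_score=0.99)
        score_out = make_variant(exomiser_rank=1, exomiser_score=0.94)
        absent = make_variant()
        assert gene_agnostic_flags(ok, HET_MAT) == {Tier.GENE_AGNOSTIC_EXOMISER}
        assert not gene_agnostic_flags(rank_out, HET_MAT)
        assert not gene_agnostic_flags(score_out, HET_MAT)
        assert not gene_agnostic_flags(absent, HET_MAT)

    def test_inherited_missense_on_panel_is_tier2(self):
        v = make_variant(gene="INTS1")
        assert assign_tier(v, HET_MAT, [R29]).tier is Tier.TIER2

    def test_synonymous_never_tiered_even_with_spliceai(self):
        v = make_variant(gene="CHAMP1", consequence="synonymous", spliceai=0.95)
        assert assign_tier(v, DN, [R29]).tier is Tier.UNTIERED

    def test_tier1_holds_tier2_flag_too(self):
        v = make_variant(gene="CHAMP1", consequence="stop_gained")
        a = assign_tier(v, DN, [R29])
        assert a.tier is Tier.TIER1
        assert Tier.TIER2 in a.flags

    def test_no_panels_only_gene_agnostic_reachable(self):
        de_novo = make_variant(gene="ANY")
        assert assign_tier(de_novo, DN, []).tier is Tier.GENE_AGNOSTIC_DENOVO
        inherited = make_variant(gene="ANY")
        assert assign_tier(inherited, HET_MAT, []).tier is Tier.UNTIERED


def test_panel_changes_are_monotone():
    """Removing a panel never adds tiered variants; adding a panel never
    removes gene-agnostic qualifications."""
    other = GeneList("R98", frozenset({"ABCC8"}), "panelapp_green")
    variants = [
        (make_variant(pos=1000 + i, gene=g, consequence=c,
                      exomiser_rank=r, exomiser_score=s), label)
        for i, (g, c, label, r, s) in enumerate(
            [
                ("CHAMP1", "stop_gained", DN, None, None),
                ("ABCC8", "stop_gained", HET_MAT, None, None),
                ("NOVEL1", "missense", DN, None, None),
                ("NOVEL2", "missense", HET_MAT, 1, 0.99),
                ("INTS1", "missense", HET_MAT, None, None),
            ]
        )
    ]
    for panels_small, panels_big in [([], [R29]), ([R29], [R29, other])]:
        for v, label in variants:
            a_small = assign_tier(v, label, panels_small)
            a_big = assign_tier(v, label, panels_big)
            tiered = {Tier.TIER1, Tier.TIER2}
            assert a_small.flags & tiered <= a_big.flags & tiered
            agnostic = {Tier.GENE_AGNOSTIC_DENOVO, Tier.GENE_AGNOSTIC_EXOMISER}
            assert a_small.flags & agnostic == a_big.flags & agnostic


def test_off_panel_cohort_contrast():
    """When every causal variant is off-panel, inherited and unranked, the
    panel strategy returns nothing while the panel-agnostic filter finds
    them — the central contrast between the approaches."""
    trio = Trio(family_id="F", proband_id="p")
    causal = [
        (make_variant(pos=1000, gene="ABCC8", consequence="stop_gained", clinvar="P"),
         make_trio("het", father="het")),
        (make_variant(pos=2000, gene="OFFP1", cadd=28, af=1e-5),
         make_trio("het", mother="het")),
    ]
    hippo_set = run_hippo(causal, trio)
    gms = run_gms(causal, trio, [R29])
    assert len(hippo_set) == 2
    assert sum(a.passing for a in gms) == 0


class TestTierACnv:
    intervals = GenomicIntervals([("1", 5_000_000, 5_050_000)])  # a green gene

    def test_small_cnv_fails_size_rule(self):
        cnv = CnvRecord("1", 5_000_000, 5_004_999)  # 5 kb
        assert not tier_a_cnv(cnv, self.intervals)

    def test_size_boundary_is_strict(self):
        at = CnvRecord("1", 5_000_000, 5_009_999)  # exactly 10 kb
        above = CnvRecord("1", 5_000_000, 5_010_000)  # 10,001 bp
        assert not tier_a_cnv(at, self.intervals)
        assert tier_a_cnv(above, self.intervals)

    def test_single_base_overlap_counts(self):
        cnv = CnvRecord("1", 4_985_001, 5_000_000)  # 15 kb, 1 bp overlap
        assert tier_a_cnv(cnv, self.intervals)

    def test_no_overlap_fails(self):
        cnv = CnvRecord("1", 8_000_000, 8_050_000)
        assert not tier_a_cnv(cnv, self.intervals)

    def test_clingen_region_rescues(self):
        clingen = GenomicIntervals([("2", 100_000, 900_000)])
        cnv = CnvRecord("2", 500_000, 520_000)
        assert not tier_a_cnv(cnv, self.intervals)
        assert tier_a_cnv(cnv, self.intervals, clingen)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            CnvRecord("1", 100, 50)
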