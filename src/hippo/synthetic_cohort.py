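"""Synthetic annotated trio cohorts with known truth labels.

Generates a joint-called multi-sample VCF, a PED file, gene lists and a
truth table so that every stage of the toolkit — VCF ingestion, inheritance
classification, both triage strategies and the comparison metrics — can be
exercised end to end without any reference data download.

What it emulates: the *annotation structure* of a joint-called, VEP-style
annotated trio VCF — per-transcript consequences with exon distances,
population and cohort allele frequencies, CADD/REVEL/SpliceAI scores,
ClinVar assertions, FILTER status and per-sample GT:AD:GQ.  What it does
not: linkage, realistic mutation rates, read-level error, or real genome
coordinates.  Coordinates are synthetic — each gene sits on its own contig
with a declared exon structure (written to a companion BED), so
distance-to-exon is computable without a reference.

Variant categories per family (mixture configurable):

* ``common_benign`` — population AF ~ U(0.01, 0.5); removed by every arm's
  frequency rules.
* ``rare_benign`` — AF < 0.001 but CADD ~ U(0, 10); removed by HiPPo's CADD
  rule, yet tiered by the panel-based strategy when the gene is on panel
  (panel tiering applies no in-silico score filter).
* ``de_novo_damaging`` — absent from population databases, CADD ~ U(20, 45),
  de novo in the proband.
* ``comp_het_pair`` — two heterozygous variants in one gene, one maternal
  and one paternal, AF ~ U(0.0015, 0.0045): above the dominant AF ceiling,
  below the recessive one, so only trans-aware recessive screening keeps
  them.
* ``clinvar_pathogenic_inherited`` — asserted Pathogenic, carried by one
  unaffected parent; retained by HiPPo's ClinVar override, but UNTIERED by
  the panel strategy whenever the gene is off panel.

Every emitted variant carries a truth row (category, inheritance label, the
expected HiPPo verdict and expected GMS tier), computed by the generator
directly from the values it drew.  Output is byte-for-byte deterministic in
the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml


@dataclass
class VariantMix:
    """Per-family counts of each simulated variant category."""

    common_benign: int = 30
    rare_benign: int = 20
    de_novo_damaging: int = 1
    comp_het_pairs: int = 1
    clinvar_pathogenic_inherited: int = 1


@dataclass
class SimulationConfig:
    seed: int = 0
    n_families: int = 3
    mix: VariantMix = field(default_factory=VariantMix)
    #: probability that a variant's gene is green on the applied panel
    on_panel_fraction: float = 0.5
    #: probability that a variant's gene is GenCC strong/definitive
    gencc_fraction: float = 0.5
    #: fraction of benign rows flagged non-PASS (joint-caller soft filters)
    nonpass_fraction: float = 0.05
    mean_depth: int = 35
    #: family structure: "trio", or a duo lacking one parent
    family_structure: str = "trio"

    def __post_init__(self) -> None:
        if isinstance(self.mix, dict):
            self.mix = VariantMix(**self.mix)
        if self.family_structure not in ("trio", "duo_mat", "duo_pat"):
            raise ValueError(f"unknown family_structure {self.family_structure!r}")
        if any(
            getattr(self.mix, f.name) < 0 for f in dataclasses.fields(self.mix)
        ):
            raise ValueError("variant counts must be >= 0")
        if self.family_structure != "trio":
            if self.mix.comp_het_pairs > 0:
                raise ValueError(
                    "compound-het pairs require both parents; "
                    "impossible with a single-parent family"
                )
            if self.mix.de_novo_damaging > 0:
                raise ValueError(
                    "de novo truth labels require both parents; "
                    "impossible with a single-parent family"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class CohortPaths:
    vcf: Path
    ped: Path
    truth: Path
    panel: Path
    gencc: Path
    genes_bed: Path


# gene model: one contig per gene, three 200 bp exons
_EXONS = ((1001, 1200), (1701, 1900), (2401, 2600))
_BASES = "ACGT"

_AF_SOURCES = ("gnomADe_AF", "gnomADg_AF", "TOPMED_AF", "ExAC_AF", "KG_AF")

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=gnomADe_AF,Number=A,Type=Float,Description="gnomAD exomes allele frequency">
##INFO=<ID=gnomADg_AF,Number=A,Type=Float,Description="gnomAD genomes allele frequency">
##INFO=<ID=TOPMED_AF,Number=A,Type=Float,Description="TOPMed allele frequency">
##INFO=<ID=ExAC_AF,Number=A,Type=Float,Description="ExAC allele frequency">
##INFO=<ID=KG_AF,Number=A,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID=cohort_AF,Number=A,Type=Float,Description="Joint-call cohort allele frequency">
##INFO=<ID=CADD_PHRED,Number=A,Type=Float,Description="CADD PHRED score">
##INFO=<ID=REVEL,Number=A,Type=Float,Description="REVEL score">
##INFO=<ID=SpliceAI_DS,Number=A,Type=Float,Description="SpliceAI max delta score">
##INFO=<ID=CLNSIG,Number=.,Type=String,Description="ClinVar clinical significance">
##INFO=<ID=ExomiserRank,Number=A,Type=Integer,Description="Exomiser rank">
##INFO=<ID=ExomiserScore,Number=A,Type=Float,Description="Exomiser score">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. Format: Allele|SYMBOL|Consequence|Feature|EXON_DISTANCE">
##FILTER=<ID=LowQual,Description="Joint-caller soft filter">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

TRUTH_COLUMNS = [
    "family",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "category",
    "label",
    "on_panel",
    "gencc",
    "expected_hippo",
    "expected_gms",
]


@dataclass
class _SimVariant:
    family: str
    gene: str
    contig: str
    pos: int
    ref: str
    alt: str
    category: str
    label: str  # inheritance truth
    consequence: str
    afs: dict[str, float]
    cohort_af: float
    cadd: Optional[float]
    clinvar: Optional[str]
    filter_status: str
    on_panel: bool
    gencc: bool
    # genotypes as (gt_string, ref_reads, alt_reads, gq) per role
    genotypes: dict[str, tuple[str, int, int, int]]


def _expected_hippo(v: _SimVariant) -> str:
    """The generator's own retention arithmetic over the drawn values
    (kept independent of :func:`hippo.hippo_filter.hippo_retain`)."""
    max_af = max(v.afs.values(), default=0.0)
    if v.clinvar in ("Pathogenic", "Likely_pathogenic") and max_af < 0.05:
        return "retain"
    mode_af = 0.05 if v.category == "comp_het_pair" else 0.001
    if max_af >= mode_af:
        return "remove"
    if v.cohort_af >= 0.01:
        return "remove"
    if v.cadd is not None and v.cadd <= 15:
        return "remove"
    if v.clinvar in ("Benign", "Likely_benign"):
        return "remove"
    return "retain"


def _expected_gms(v: _SimVariant) -> str:
    """Expected tier under the panel-based strategy (its screening has no
    trans-awareness, so inherited hets face the dominant AF ceiling)."""
    max_af = max(v.afs.values(), default=0.0)
    de_novo = v.label == "de_novo"
    if max_af >= 0.001:
        return "prefilter_fail"
    agnostic = de_novo  # coding by construction; no Exomiser annotations drawn
    if not agnostic and v.filter_status != "PASS":
        return "prefilter_fail"
    plof = v.consequence in ("stop_gained", "frameshift", "frameshift_variant")
    if v.on_panel and (plof or de_novo):
        return "TIER1"
    if v.on_panel:
        return "TIER2"
    if de_novo:
        return "GENE_AGNOSTIC_DENOVO"
    return "UNTIERED"


def generate_cohort(cfg: SimulationConfig, out_dir: str | Path) -> CohortPaths:
    """Generate the cohort files under ``out_dir`` and return their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    families = [f"SIM{f:02d}" for f in range(1, cfg.n_families + 1)]
    roles = ["p", "m", "f"]
    if cfg.family_structure == "duo_mat":
        roles = ["p", "m"]
    elif cfg.family_structure == "duo_pat":
        roles = ["p", "f"]
    samples = [f"{fam}_{r}" for fam in families for r in roles]

    gene_counter = 0

    def new_gene() -> tuple[str, str, bool, bool]:
        nonlocal gene_counter
        name = f"GENE{gene_counter:05d}"
        contig = f"ctg{gene_counter:05d}"
        gene_counter += 1
        on_panel = bool(rng.random() < cfg.on_panel_fraction)
        gencc = bool(rng.random() < cfg.gencc_fraction)
        return name, contig, on_panel, gencc

    def draw_site(rng) -> tuple[int, str, str]:
        exon = _EXONS[rng.integers(len(_EXONS))]
        pos = int(rng.integers(exon[0], exon[1] + 1))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        return pos, str(ref), str(alt)

    def het_depths() -> tuple[int, int, int]:
        ref_d = int(rng.integers(12, 26))
        alt_d = int(rng.integers(12, 26))
        gq = int(rng.integers(50, 100))
        return ref_d, alt_d, gq

    def hom_ref_call() -> tuple[str, int, int, int]:
        return ("0/0", int(rng.integers(25, 45)), 0, int(rng.integers(50, 100)))

    def het_call() -> tuple[str, int, int, int]:
        r, a, gq = het_depths()
        return ("0/1", r, a, gq)

    variants: list[_SimVariant] = []
    for fam in families:
        parent_roles = [r for r in roles if r != "p"]

        def add_variant(
            category: str,
            consequence: str,
            afs: dict[str, float],
            cohort_af: float,
            cadd: Optional[float],
            clinvar: Optional[str],
            label: str,
            genotypes: dict[str, tuple[str, int, int, int]],
            filter_status: str = "PASS",
            gene_info: Optional[tuple[str, str, bool, bool]] = None,
            pos_override: Optional[tuple[int, str, str]] = None,
        ) -> None:
            gene, contig, on_panel, gencc = gene_info or new_gene()
            pos, ref, alt = pos_override or draw_site(rng)
            variants.append(
                _SimVariant(
                    family=fam,
                    gene=gene,
                    contig=contig,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    category=category,
                    label=label,
                    consequence=consequence,
                    afs=afs,
                    cohort_af=cohort_af,
                    cadd=cadd,
                    clinvar=clinvar,
                    filter_status=filter_status,
                    on_panel=on_panel,
                    gencc=gencc,
                    genotypes=genotypes,
                )
            )

        def inherited_het_genotypes(parent: str) -> tuple[str, dict]:
            gts = {"p": het_call()}
            for r in parent_roles:
                gts[r] = het_call() if r == parent else hom_ref_call()
            label = "inherited_het_mat" if parent == "m" else "inherited_het_pat"
            if len(parent_roles) < 2:
                # single-parent family: the carrier parent is still known
                label = "inherited_het_mat" if parent == "m" else "inherited_het_pat"
            return label, gts

        def maybe_nonpass() -> str:
            return "LowQual" if rng.random() < cfg.nonpass_fraction else "PASS"

        for _ in range(cfg.mix.common_benign):
            base = float(rng.uniform(0.01, 0.5))
            afs = {
                src: float(np.clip(base * rng.uniform(0.8, 1.2), 0.0, 1.0))
                for src in _AF_SOURCES
            }
            parent = parent_roles[int(rng.integers(len(parent_roles)))]
            label, gts = inherited_het_genotypes(parent)
            add_variant(
                "common_benign",
                "missense_variant",
                afs,
                cohort_af=base,
                cadd=float(rng.uniform(0, 30)),
                clinvar=None,
                label=label,
                genotypes=gts,
                filter_status=maybe_nonpass(),
            )

        for _ in range(cfg.mix.rare_benign):
            base = float(rng.uniform(1e-6, 4e-4))
            afs = {
                src: float(base * rng.uniform(0.8, 1.2)) for src in _AF_SOURCES
            }
            parent = parent_roles[int(rng.integers(len(parent_roles)))]
            label, gts = inherited_het_genotypes(parent)
            add_variant(
                "rare_benign",
                "missense_variant",
                afs,
                cohort_af=float(rng.uniform(0, 0.005)),
                cadd=float(rng.uniform(0, 10)),
                clinvar=None,
                label=label,
                genotypes=gts,
                filter_status=maybe_nonpass(),
            )

        for _ in range(cfg.mix.de_novo_damaging):
            consequence = str(
                rng.choice(["missense_variant", "stop_gained", "frameshift_variant"])
            )
            gts = {"p": het_call(), "m": hom_ref_call(), "f": hom_ref_call()}
            add_variant(
                "de_novo_damaging",
                consequence,
                afs={},
                cohort_af=float(rng.uniform(0, 1e-4)),
                cadd=float(rng.uniform(20, 45)),
                clinvar=None,
                label="de_novo",
                genotypes=gts,
            )

        for _ in range(cfg.mix.comp_het_pairs):
            gene_info = new_gene()
            site1 = draw_site(rng)
            site2 = draw_site(rng)
            while site2[0] == site1[0]:
                site2 = draw_site(rng)
            sites = sorted([site1, site2])
            for site, parent in zip(sites, ("m", "f")):
                base = float(rng.uniform(0.0015, 0.0045))
                afs = {
                    src: float(base * rng.uniform(0.9, 1.1)) for src in _AF_SOURCES
                }
                label, gts = inherited_het_genotypes(parent)
                add_variant(
                    "comp_het_pair",
                    "missense_variant",
                    afs,
                    cohort_af=float(rng.uniform(0, 0.008)),
                    cadd=float(rng.uniform(20, 40)),
                    clinvar=None,
                    label=label,
                    genotypes=gts,
                    gene_info=gene_info,
                    pos_override=site,
                )

        for _ in range(cfg.mix.clinvar_pathogenic_inherited):
            base = float(rng.uniform(0, 4e-4))
            afs = {src: float(base * rng.uniform(0.8, 1.2)) for src in _AF_SOURCES}
            parent = parent_roles[int(rng.integers(len(parent_roles)))]
            label, gts = inherited_het_genotypes(parent)
            cadd = float(rng.uniform(10, 40)) if rng.random() < 0.7 else None
            add_variant(
                "clinvar_pathogenic_inherited",
                "stop_gained",
                afs,
                cohort_af=float(rng.uniform(0, 1e-3)),
                cadd=cadd,
                clinvar="Pathogenic",
                label=label,
                genotypes=gts,
            )

    variants.sort(key=lambda v: (v.contig, v.pos, v.alt))

    # ---- write VCF -------------------------------------------------------
    vcf_path = out_dir / "cohort.vcf"
    contigs = sorted({v.contig for v in variants})
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig},length=3600>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t")
        fh.write("FORMAT\t" + "\t".join(samples) + "\n")
        for v in variants:
            info = []
            for src, af in v.afs.items():
                info.append(f"{src}={af:.6g}")
            info.append(f"cohort_AF={v.cohort_af:.6g}")
            if v.cadd is not None:
                info.append(f"CADD_PHRED={v.cadd:.3g}")
            if v.clinvar is not None:
                info.append(f"CLNSIG={v.clinvar}")
            info.append(
                f"CSQ={v.alt}|{v.gene}|{v.consequence}|{v.gene}.t1|0"
            )
            calls = []
            for sample in samples:
                fam_role = sample.rsplit("_", 1)
                if fam_role[0] == v.family:
                    gt, r, a, gq = v.genotypes[fam_role[1]]
                else:
                    gt, r, a, gq = "0/0", 30, 0, 60
                calls.append(f"{gt}:{r},{a}:{gq}")
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t100\t"
                f"{'.' if v.filter_status == 'PASS' else v.filter_status}\t"
                f"{';'.join(info)}\tGT:AD:GQ\t" + "\t".join(calls) + "\n"
            )

    # ---- write PED -------------------------------------------------------
    ped_path = out_dir / "cohort.ped"
    with open(ped_path, "w") as fh:
        for fam in families:
            father = f"{fam}_f" if "f" in roles else "0"
            mother = f"{fam}_m" if "m" in roles else "0"
            fh.write(f"{fam}\t{fam}_p\t{father}\t{mother}\t1\t2\n")
            if "m" in roles:
                fh.write(f"{fam}\t{fam}_m\t0\t0\t2\t1\n")
            if "f" in roles:
                fh.write(f"{fam}\t{fam}_f\t0\t0\t1\t1\n")

    # ---- write truth table ----------------------------------------------
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        v.family,
                        v.contig,
                        v.pos,
                        v.ref,
                        v.alt,
                        v.gene,
                        v.category,
                        v.label,
                        int(v.on_panel),
                        int(v.gencc),
                        _expected_hippo(v),
                        _expected_gms(v),
                    )
                )
                + "\n"
            )

    # ---- gene lists and exon BED ----------------------------------------
    genes = sorted({(v.gene, v.contig, v.on_panel, v.gencc) for v in variants})
    panel_path = out_dir / "panel.tsv"
    with open(panel_path, "w") as fh:
        fh.write("gene\tconfidence\n")
        for gene, _, on_panel, _ in genes:
            fh.write(f"{gene}\t{'green' if on_panel else 'red'}\n")
    gencc_path = out_dir / "gencc.tsv"
    with open(gencc_path, "w") as fh:
        fh.write("gene\tclassification\n")
        for gene, _, _, gencc in genes:
            fh.write(f"{gene}\t{'Definitive' if gencc else 'Limited'}\n")
    bed_path = out_dir / "genes.bed"
    with open(bed_path, "w") as fh:
        for gene, contig, _, _ in genes:
            for start, end in _EXONS:
                fh.write(f"{contig}\t{start - 1}\t{end}\t{gene}\n")

    return CohortPaths(
        vcf=vcf_path,
        ped=ped_path,
        truth=truth_path,
        panel=panel_path,
        gencc=gencc_path,
        genes_bed=bed_path,
    )


# re-exported here because the packaged study tables are the other half of
# the test fixture surface
from hippo.fixtures import study_tables  # noqa: E402,F401
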