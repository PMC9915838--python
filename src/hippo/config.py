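"""Filtering thresholds for both triage strategies.

Every numeric threshold used anywhere in the toolkit lives here, keyed by
strategy and inheritance mode; no rule implementation hard-codes a cut-off.
The two shipped presets are:

* :meth:`FilterConfig.hippo` — the panel-agnostic research filter: population
  AF < 0.001 (dominant) / < 0.05 (recessive), cohort AF < 0.01, coding
  consequences within +/- 20 bp of an exon (excluding synonymous),
  SpliceAI > 0.2 for splicing variants, CADD > 15, benign/likely-benign
  ClinVar assertions removed, proband allele balance > 0.2 and GQ > 40, no
  PASS requirement, with ClinVar P/LP variants retained even when carried by
  an unaffected parent.
* :meth:`FilterConfig.gms` — the NHS panel-based pre-filter: AF < 0.001
  (dominant) / < 0.01 (recessive), coding +/- 8 bp excluding synonymous,
  GQ > 30, PASS only, no in-silico score or ClinVar rules, plus the
  gene-agnostic channel thresholds (Exomiser rank <= 3 with score >= 0.95)
  and the > 10 kb CNV size rule.

All comparisons are strict inequalities as printed in the source thresholds
(">0.2" means 0.2 fails) except the Exomiser score, which is an inclusive
">= 0.95".
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from hippo.records import DEFAULT_PLOF_TERMS

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    strategy: str = "hippo"

    # population allele-frequency ceilings (max over all AF sources)
    af_max_dominant: float = 0.001
    af_max_recessive: float = 0.05
    # joint-called cohort allele-frequency ceiling; None = no filter
    cohort_af_max: Optional[float] = 0.01

    # locational rule: coding or within +/- N bp of an exon edge
    coding_window_bp: int = 20

    # in-silico score thresholds; None = rule not applied
    spliceai_min: Optional[float] = 0.2
    cadd_min: Optional[float] = 15.0

    # ClinVar handling
    remove_benign: bool = True
    clinvar_override: bool = True
    #: safety ceiling: even an asserted-pathogenic variant is dropped above
    #: this population AF (guards against miscurated common variants)
    clinvar_override_af_ceiling: float = 0.05

    # genotype-level quality rules; None = rule not applied
    allele_balance_min: Optional[float] = 0.2
    gq_min: Optional[int] = 40
    #: apply the GQ rule to parents as well as the proband
    gq_all_members: bool = False
    require_pass: bool = False

    # GMS gene-agnostic channel
    exomiser_score_min: float = 0.95
    exomiser_rank_max: int = 3

    # GMS Tier A CNV rule
    cnv_min_size_bp: int = 10_000

    #: consequence terms counted as predicted loss-of-function
    plof_terms: frozenset[str] = field(default_factory=lambda: DEFAULT_PLOF_TERMS)

    #: annotation transcript set the consequences were computed on (RefSeq or
    #: Ensembl); declared, not defaulted to a claim of correctness
    transcript_set: Optional[str] = None

    def af_max(self, mode: str) -> float:
        if mode == "dominant":
            return self.af_max_dominant
        if mode == "recessive":
            return self.af_max_recessive
        raise ValueError(f"unknown inheritance mode {mode!r}")

    @classmethod
    def hippo(cls, **overrides) -> "FilterConfig":
        """Panel-agnostic research-exome preset."""
        cfg = cls(strategy="hippo")
        return cfg.with_overrides(**overrides)

    @classmethod
    def gms(cls, **overrides) -> "FilterConfig":
        """NHS genome panel-based preset."""
        cfg = cls(
            strategy="gms",
            af_max_dominant=0.001,
            af_max_recessive=0.01,
            cohort_af_max=None,
            coding_window_bp=8,
            spliceai_min=None,
            cadd_min=None,
            remove_benign=False,
            clinvar_override=False,
            allele_balance_min=None,
            gq_min=30,
            require_pass=True,
        )
        return cfg.with_overrides(**overrides)

    def with_overrides(self, **overrides) -> "FilterConfig":
        """Return a copy with the given fields replaced; overrides logged."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise TypeError(f"unknown FilterConfig fields: {sorted(unknown)}")
        for key, value in overrides.items():
            if getattr(self, key) != value:
                log.info(
                    "threshold override: %s %s -> %s", key, getattr(self, key), value
                )
        return dataclasses.replace(self, **overrides)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["plof_terms"] = sorted(self.plof_terms)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        d = dict(d)
        strategy = d.pop("strategy", "hippo")
        if "plof_terms" in d:
            d["plof_terms"] = frozenset(d["plof_terms"])
        base = cls.hippo() if strategy == "hippo" else cls.gms()
        return base.with_overrides(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
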