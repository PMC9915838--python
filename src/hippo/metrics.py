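"""Strategy-comparison statistics: rates per variant assessed and paired tests.

The central efficiency metric is the *diagnostic rate per variant assessed*:
pathogenic diagnoses divided by the number of variants a laboratory had to
review after filtering.  A strategy that reviews 15 variants to find 3
diagnoses (20%) is more efficient than one reviewing 63 to find 2 (3.17%),
even if both find the same patients' diagnoses.

Per-family assessed counts from the two strategies are compared with a
paired Wilcoxon signed-rank test.  Two methods are provided:

* ``normal_cc`` (default) — normal approximation with continuity correction
  and the tie-variance correction, zero differences dropped;
* ``exact`` — full enumeration of all ``2^n`` sign assignments over the
  mid-ranked absolute differences.

For small samples with ties the two can differ noticeably; both are exposed
so the convention is always explicit.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


def rate_per_assessed(n_hits: int, n_assessed: int) -> float:
    """Percentage of assessed variants that were hits: ``100 * h / n``.

    Raises :class:`ValueError` when nothing was assessed (the rate is
    undefined, not zero).
    """
    if n_assessed <= 0:
        raise ValueError("rate undefined: n_assessed must be > 0")
    if n_hits < 0 or n_hits > n_assessed:
        raise ValueError(f"n_hits={n_hits} outside [0, {n_assessed}]")
    return 100.0 * n_hits / n_assessed


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # V: sum of ranks of positive differences
    p_value: float
    method: str
    n_nonzero: int


def _signed_ranks(pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    """Signed mid-ranks of the non-zero paired differences."""
    d = np.asarray([a - b for a, b in pairs], dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return d
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    return np.sign(d) * ranks


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]],
    method: str = "normal_cc",
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped before ranking; ties among the remaining
    absolute differences receive mid-ranks.  The returned statistic is V,
    the sum of ranks of the positive differences.

    ``normal_cc`` uses the normal approximation with continuity correction
    and tie-variance correction (delegated to :func:`scipy.stats.wilcoxon`);
    ``exact`` enumerates all ``2^n`` sign assignments of the rank vector,
    which also handles ties exactly.  With every difference zero the test is
    vacuous: V = 0, p = 1, with a warning.
    """
    if method not in ("normal_cc", "exact"):
        raise ValueError(f"unknown method {method!r}")

    signed = _signed_ranks(pairs)
    n = signed.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, method, 0)
    if n < 3:
        raise ValueError(f"need >= 3 non-zero differences, got {n}")

    v = float(signed[signed > 0].sum())

    if method == "normal_cc":
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=True, method="approx"
        )
        return WilcoxonResult(v, float(res.pvalue), method, n)

    # exact: distribution of V over all sign assignments of |d| ranks
    abs_ranks = np.abs(signed)
    total = 0
    le = 0  # assignments with V' <= v
    ge = 0  # assignments with V' >= v
    for signs in itertools.product((0.0, 1.0), repeat=n):
        vp = float(np.dot(signs, abs_ranks))
        total += 1
        if vp <= v + 1e-9:
            le += 1
        if vp >= v - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return WilcoxonResult(v, p, method, n)


# ---------------------------------------------------------------------------
# Strategy comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportedVariant:
    """One variant placed on a report, with its curation outcome."""

    family: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    classification: str = "VUS"  # P / LP / VUS
    #: accepted as explaining (or partially explaining) the phenotype —
    #: a consumed clinical judgement, never inferred here
    diagnostic: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ComparisonResult:
    """Cohort-level head-to-head of the two triage strategies."""

    families: list[str]
    dropped_families: list[str]
    per_family: dict[str, dict[str, Optional[int]]]

    hippo_assessed: int
    gms_assessed: int
    gencc_assessed: Optional[int]

    hippo_diagnostic: int
    gms_diagnostic: int
    hippo_reportable: int
    gms_reportable: int

    diagnostic_rate_hippo: float
    diagnostic_rate_gms: float
    reportable_rate_hippo: float
    reportable_rate_gms: float
    diagnostic_rate_gencc: Optional[float]
    reportable_rate_gencc: Optional[float]

    overlap: int
    wilcoxon_all: Optional[WilcoxonResult] = None
    wilcoxon_gencc: Optional[WilcoxonResult] = None

    def to_dict(self) -> dict:
        d = {
            "families": self.families,
            "dropped_families": self.dropped_families,
            "per_family": self.per_family,
            "assessed": {
                "hippo": self.hippo_assessed,
                "gms": self.gms_assessed,
                "hippo_gencc": self.gencc_assessed,
            },
            "diagnostic": {"hippo": self.hippo_diagnostic, "gms": self.gms_diagnostic},
            "reportable": {"hippo": self.hippo_reportable, "gms": self.gms_reportable},
            "rates_percent": {
                "diagnostic_hippo": self.diagnostic_rate_hippo,
                "diagnostic_gms": self.diagnostic_rate_gms,
                "diagnostic_hippo_gencc": self.diagnostic_rate_gencc,
                "reportable_hippo": self.reportable_rate_hippo,
                "reportable_gms": self.reportable_rate_gms,
                "reportable_hippo_gencc": self.reportable_rate_gencc,
            },
            "overlap": self.overlap,
        }
        for name, res in (("all_genes", self.wilcoxon_all), ("gencc", self.wilcoxon_gencc)):
            if res is not None:
                d.setdefault("wilcoxon", {})[name] = {
                    "V": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                    "n": res.n_nonzero,
                }
        return d


def compare_strategies(
    hippo_assessed: Mapping[str, Optional[int]],
    gms_assessed: Mapping[str, Optional[int]],
    hippo_reported: Iterable[ReportedVariant],
    gms_reported: Iterable[ReportedVariant],
    gencc_assessed: Optional[Mapping[str, Optional[int]]] = None,
    incomparable: Iterable[str] = (),
    method: str = "normal_cc",
) -> ComparisonResult:
    """Compare the two strategies on the families both analysed.

    ``*_assessed`` map family id to the number of variants that strategy
    left for review (CNVs excluded by the caller — they are not assessed in
    both arms).  A family missing (or ``None``) in either arm, or listed in
    ``incomparable`` (e.g. trio structures differing between arms), is
    dropped from all paired counts and tests with a warning.  Reported
    variants outside the compared families are ignored.

    Rates follow the headline arithmetic of the comparison: the GenCC rates
    divide the *same* diagnostic / reportable numerators by the
    GenCC-restricted assessed denominator.

    Overlap counts (chrom, pos, ref, alt) identities reported by both
    strategies.
    """
    hippo_reported = list(hippo_reported)
    gms_reported = list(gms_reported)

    all_fams = sorted(set(hippo_assessed) | set(gms_assessed))
    families, dropped = [], []
    incomparable = set(incomparable)
    for fam in all_fams:
        h, g = hippo_assessed.get(fam), gms_assessed.get(fam)
        if h is None or g is None:
            log.warning("family %s present in one arm only; dropped", fam)
            dropped.append(fam)
        elif fam in incomparable:
            log.warning("family %s flagged incomparable; dropped", fam)
            dropped.append(fam)
        else:
            families.append(fam)
    fam_set = set(families)

    per_family = {
        fam: {
            "hippo": hippo_assessed.get(fam),
            "gms": gms_assessed.get(fam),
            "hippo_gencc": gencc_assessed.get(fam) if gencc_assessed else None,
        }
        for fam in all_fams
    }

    h_total = sum(hippo_assessed[f] for f in families)
    g_total = sum(gms_assessed[f] for f in families)
    gencc_total = (
        sum(gencc_assessed[f] for f in families) if gencc_assessed else None
    )

    h_rep = [r for r in hippo_reported if r.family in fam_set]
    g_rep = [r for r in gms_reported if r.family in fam_set]
    h_diag = sum(r.diagnostic for r in h_rep)
    g_diag = sum(r.diagnostic for r in g_rep)

    overlap_keys = {r.key for r in hippo_reported} & {r.key for r in gms_reported}
    overlap = len(overlap_keys)
    assert overlap <= min(len(set(hippo_reported)), len(set(gms_reported)))

    def _paired_test(pairs):
        if len(pairs) < 3:
            return None
        try:
            return wilcoxon_signed_rank(pairs, method)
        except ValueError:  # fewer than 3 non-zero differences
            log.warning("too few non-zero differences for a paired test")
            return None

    wilcoxon_all = _paired_test([(hippo_assessed[f], gms_assessed[f]) for f in families])
    wilcoxon_gencc = None
    if gencc_assessed is not None:
        wilcoxon_gencc = _paired_test(
            [(gencc_assessed[f], gms_assessed[f]) for f in families]
        )

    return ComparisonResult(
        families=families,
        dropped_families=dropped,
        per_family=per_family,
        hippo_assessed=h_total,
        gms_assessed=g_total,
        gencc_assessed=gencc_total,
        hippo_diagnostic=h_diag,
        gms_diagnostic=g_diag,
        hippo_reportable=len(h_rep),
        gms_reportable=len(g_rep),
        diagnostic_rate_hippo=rate_per_assessed(h_diag, h_total),
        diagnostic_rate_gms=rate_per_assessed(g_diag, g_total),
        reportable_rate_hippo=rate_per_assessed(len(h_rep), h_total),
        reportable_rate_gms=rate_per_assessed(len(g_rep), g_total),
        diagnostic_rate_gencc=(
            rate_per_assessed(h_diag, gencc_total) if gencc_total else None
        ),
        reportable_rate_gencc=(
            rate_per_assessed(len(h_rep), gencc_total) if gencc_total else None
        ),
        overlap=overlap,
        wilcoxon_all=wilcoxon_all,
        wilcoxon_gencc=wilcoxon_gencc,
    )
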