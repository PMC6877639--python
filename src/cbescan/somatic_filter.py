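"""Clone-vs-parental somatic variant decision.

A candidate site carries read support from the edited clone (the "tumor"
sample, in tumor/normal-caller terminology) and from the parental line (the
"normal").  A site is retained as a somatic call when all four criteria hold,
each with a strict inequality:

* one-sided Fisher exact p < ``max_p`` (default 0.001),
* parental (normal) variant allele fraction < ``max_normal_vaf`` (default 5%),
* clone (tumor) variant allele fraction > ``min_tumor_vaf`` (default 1/3),
* clone alt-supporting reads > ``min_tumor_alt_reads`` (default 6).

The Fisher test is one-sided for enrichment of the alt allele in the clone;
a two-sided variant is available via ``alternative="two-sided"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .genome_io import PairedSiteCounts, VariantCatalog

#: "variant allele frequency in tumor" > 33.33% interpreted as the exact
#: fraction 1/3; the printed decimal is available for sensitivity checks.
TUMOR_VAF_EXACT_THIRD = 1.0 / 3.0
TUMOR_VAF_PRINTED = 0.3333


@dataclass(frozen=True)
class FilterThresholds:
    """The four somatic-call retention thresholds (all compared strictly)."""

    max_p: float = 0.001
    max_normal_vaf: float = 0.05
    min_tumor_vaf: float = TUMOR_VAF_EXACT_THIRD
    min_tumor_alt_reads: int = 6

    def __post_init__(self):
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")
        if not 0 <= self.max_normal_vaf < self.min_tumor_vaf <= 1:
            raise ValueError("need 0 <= max_normal_vaf < min_tumor_vaf <= 1")
        if self.min_tumor_alt_reads < 0:
            raise ValueError("min_tumor_alt_reads must be >= 0")


@dataclass(frozen=True)
class SomaticCall:
    """Audit record for one evaluated site."""

    site: PairedSiteCounts
    p_value: float
    tumor_vaf: float
    normal_vaf: float
    verdict: str  # "retained" | "rejected"
    rejection_reasons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        expected = "retained" if not self.rejection_reasons else "rejected"
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with rejection reasons")


def fisher_somatic_p(site: PairedSiteCounts, alternative: str = "greater") -> float:
    """One-sided Fisher exact p-value that the clone is enriched for the alt allele.

    The 2x2 table is [[tumor_alt, tumor_ref], [normal_alt, normal_ref]]; the
    default alternative is "greater" (tumor alt fraction exceeds normal).
    Both samples must have positive depth.
    """
    if site.tumor_depth == 0 or site.normal_depth == 0:
        raise ValueError(
            f"zero depth at {site.chrom}:{site.pos} "
            f"(tumor {site.tumor_depth}, normal {site.normal_depth})")
    table = [[site.tumor_alt_reads, site.tumor_ref_reads],
             [site.normal_alt_reads, site.normal_ref_reads]]
    return float(fisher_exact(table, alternative=alternative).pvalue)


def evaluate_site(site: PairedSiteCounts,
                  thresholds: FilterThresholds = FilterThresholds(),
                  alternative: str = "greater") -> SomaticCall:
    """Score one site against all four criteria, recording every failure."""
    p = fisher_somatic_p(site, alternative=alternative)
    tumor_vaf = site.tumor_alt_reads / site.tumor_depth
    normal_vaf = site.normal_alt_reads / site.normal_depth
    reasons = set()
    if not p < thresholds.max_p:
        reasons.add("p")
    if not normal_vaf < thresholds.max_normal_vaf:
        reasons.add("normal_vaf")
    if not tumor_vaf > thresholds.min_tumor_vaf:
        reasons.add("tumor_vaf")
    if not site.tumor_alt_reads > thresholds.min_tumor_alt_reads:
        reasons.add("alt_reads")
    verdict = "retained" if not reasons else "rejected"
    return SomaticCall(site, p, tumor_vaf, normal_vaf, verdict, frozenset(reasons))


def filter_somatic(sites: Iterable[PairedSiteCounts],
                   thresholds: FilterThresholds = FilterThresholds(),
                   clone_id: str = "clone",
                   alternative: str = "greater",
                   ) -> tuple[VariantCatalog, list[SomaticCall]]:
    """Apply the somatic filter to every site.

    Returns the retained calls as a sorted :class:`VariantCatalog` together
    with the complete per-site audit trail (one :class:`SomaticCall` per
    input, in input order).
    """
    calls = [evaluate_site(s, thresholds, alternative) for s in sites]
    retained = VariantCatalog(
        clone_id,
        (c.site.to_variant() for c in calls if c.verdict == "retained"),
        provenance=f"somatic filter: {thresholds}")
    return retained, calls


def calls_to_frame(calls: Sequence[SomaticCall]) -> pd.DataFrame:
    """Audit table (one row per evaluated site) for TSV export."""
    return pd.DataFrame(
        [(c.site.chrom, c.site.pos + 1, c.site.ref_allele, c.site.alt_allele,
          c.site.tumor_ref_reads, c.site.tumor_alt_reads,
          c.site.normal_ref_reads, c.site.normal_alt_reads,
          c.p_value, c.tumor_vaf, c.normal_vaf, c.verdict,
          ",".join(sorted(c.rejection_reasons)))
         for c in calls],
        columns=["chrom", "pos", "ref", "alt", "t_ref", "t_alt", "n_ref",
                 "n_alt", "p_value", "tumor_vaf", "normal_vaf", "verdict",
                 "reasons"])
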