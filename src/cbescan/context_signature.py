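"""Sequence context around mutated cytosines: logos and TCW (APOBEC) statistics.

Every context is strand-normalized so the mutated base reads C: a variant
whose reference base is G is read on the reverse complement, making
"downstream" the 3' side of the deaminated strand.  From a set of oriented
contexts the module builds a position frequency matrix with per-position
information content (the sequence-logo statistic, 2 - H bits), and measures
enrichment of the APOBEC-associated TCW motif (T at -1, A or T at +1 of the
mutated C) against the genome's own TCW background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .genome_io import Genome, Variant, VariantCatalog, revcomp

BASES = ("A", "C", "G", "T")

#: Classes whose mutated base is a cytosine on the oriented strand.
CYTOSINE_CLASSES = ("C:G>T:A", "C:G>G:C")


@dataclass(frozen=True)
class ContextWindow:
    """Flanking window around the mutated C: ``upstream`` 5' and ``downstream`` 3' bases."""

    upstream: int = 5
    downstream: int = 25

    def __post_init__(self):
        if self.upstream < 1 or self.downstream < 1:
            raise ValueError("window must extend at least 1 base on each side")

    @property
    def length(self) -> int:
        return self.upstream + 1 + self.downstream


@dataclass(frozen=True)
class OrientedContext:
    """A context sequence on the strand where the mutated base reads C."""

    sequence: str
    center_index: int
    source_variant: Variant

    def __post_init__(self):
        if self.sequence[self.center_index] != "C":
            raise ValueError("center base must read C on the oriented strand")
        if "N" in self.sequence:
            raise ValueError("N-containing contexts must be excluded upstream")


@dataclass(frozen=True)
class ExcludedContext:
    """A variant whose window could not be extracted, with the reason."""

    source_variant: Variant
    reason: str  # "out_of_bounds" | "contains_N"


@dataclass
class ContextMatrix:
    """Position frequency matrix and information-content profile.

    ``positions`` run from -upstream to +downstream with the mutated C at 0;
    ``freq`` is (n_positions, 4) over A/C/G/T; ``info_bits`` is 2 - H per
    position (optionally minus the small-sample correction e(n)).
    """

    positions: np.ndarray
    freq: np.ndarray
    info_bits: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=[f"f{b}" for b in BASES])
        df.insert(0, "position", self.positions)
        df["bits"] = self.info_bits
        return df


def extract_context(genome: Genome, variant: Variant,
                    window: ContextWindow = ContextWindow(),
                    ) -> OrientedContext | ExcludedContext:
    """Oriented flanking sequence of a C:G SNV, or an exclusion record.

    For ref C the context is read on the plus strand; for ref G it is the
    reverse complement, so position 0 reads C and positive offsets are 3' of
    the mutated base on that strand.  Windows leaving the chromosome or
    containing N are excluded (never padded), with the reason recorded.
    """
    if not variant.is_snv or variant.ref not in ("C", "G"):
        raise ValueError(
            f"context extraction needs a C:G-site SNV, got {variant.ref}>{variant.alt}")
    length = len(genome.sequences[variant.chrom]) if variant.chrom in genome else None
    if length is None:
        raise ValueError(f"unknown chromosome {variant.chrom!r}")
    if variant.ref == "C":
        start, end = variant.pos - window.upstream, variant.pos + window.downstream + 1
    else:  # ref G: window extends upstream on the plus strand, then flipped
        start, end = variant.pos - window.downstream, variant.pos + window.upstream + 1
    if start < 0 or end > length:
        return ExcludedContext(variant, "out_of_bounds")
    seq = genome.fetch(variant.chrom, start, end)
    if variant.ref == "G":
        seq = revcomp(seq)
    if "N" in seq:
        return ExcludedContext(variant, "contains_N")
    return OrientedContext(seq, window.upstream, variant)


def extract_contexts(genome: Genome, catalog: VariantCatalog,
                     window: ContextWindow = ContextWindow(),
                     classes: Sequence[str] = CYTOSINE_CLASSES,
                     ) -> tuple[list[OrientedContext], list[ExcludedContext]]:
    """Contexts for every SNV of the requested C:G classes in a catalog."""
    from .spectrum import classify_substitution

    kept, excluded = [], []
    for v in catalog:
        if not v.is_snv or v.ref not in ("C", "G"):
            continue
        if classify_substitution(v.ref, v.alt) not in classes:
            continue
        result = extract_context(genome, v, window)
        (kept if isinstance(result, OrientedContext) else excluded).append(result)
    return kept, excluded


def small_sample_correction(n: int) -> float:
    """e(n) = 3 / (2 ln2 n), the small-sample entropy bias term."""
    return 3.0 / (2.0 * math.log(2.0) * n)


def build_context_matrix(contexts: Sequence[OrientedContext | str],
                         correction: str = "none",
                         center_index: int | None = None) -> ContextMatrix:
    """Column frequencies and information content from equal-length contexts.

    info_bits(position) = 2 - H(position), H the Shannon entropy over observed
    base frequencies; with ``correction="small_sample"`` the bias term
    e(n) = 3/(2 ln2 n) is subtracted and the result floored at 0.
    """
    if not contexts:
        raise ValueError("need at least one context")
    if correction not in ("none", "small_sample"):
        raise ValueError(f"unknown correction {correction!r}")
    seqs = [c.sequence if isinstance(c, OrientedContext) else c for c in contexts]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("contexts have unequal lengths")
    if center_index is None:
        center_index = (contexts[0].center_index
                        if isinstance(contexts[0], OrientedContext) else L // 2)
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    freq = np.stack([(arr == b.encode()).mean(axis=0) for b in BASES], axis=1)
    logf = np.log2(np.where(freq > 0, freq, 1.0))  # 0*log(0) treated as 0
    entropy = -(freq * logf).sum(axis=1)
    bits = 2.0 - entropy
    if correction == "small_sample":
        bits = np.maximum(bits - small_sample_correction(len(seqs)), 0.0)
    positions = np.arange(L) - center_index
    return ContextMatrix(positions, freq, bits, len(seqs))


def is_tcw(context: OrientedContext | str, center_index: int | None = None) -> bool:
    """True iff the oriented context has T at -1 and A or T at +1."""
    seq = context.sequence if isinstance(context, OrientedContext) else context
    ci = (context.center_index if isinstance(context, OrientedContext)
          else (len(seq) // 2 if center_index is None else center_index))
    if ci < 1 or ci + 1 >= len(seq):
        raise ValueError("context window too small to read positions -1/+1")
    return seq[ci - 1] == "T" and seq[ci + 1] in ("A", "T")


def tcw_fraction(contexts: Sequence[OrientedContext | str],
                 center_index: int | None = None) -> float:
    """Fraction of oriented contexts matching the TCW motif."""
    if not contexts:
        raise ValueError("no contexts")
    return sum(is_tcw(c, center_index) for c in contexts) / len(contexts)


def genome_tcw_background(genome: Genome) -> float:
    """Fraction of genomic cytosines (both strands) in TCW trinucleotide context.

    Plus strand: T-C-[A/T]; minus strand (a plus-strand G): [T/A]-G-A read on
    the plus strand.  Cytosines without a complete N-free trinucleotide are
    excluded from both numerator and denominator.
    """
    tcw = 0
    total = 0
    for seq in genome.sequences.values():
        if len(seq) < 3:
            continue
        a = np.frombuffer(seq.encode(), dtype="S1")
        left, mid, right = a[:-2], a[1:-1], a[2:]
        valid = (left != b"N") & (right != b"N")
        is_c = (mid == b"C") & valid
        is_g = (mid == b"G") & valid
        total += int(is_c.sum() + is_g.sum())
        tcw += int((is_c & (left == b"T") & ((right == b"A") | (right == b"T"))).sum())
        tcw += int((is_g & (right == b"A") & ((left == b"T") | (left == b"A"))).sum())
    if total == 0:
        raise ValueError("genome has no cytosine with a complete trinucleotide context")
    return tcw / total


@dataclass(frozen=True)
class TcwEnrichment:
    observed_fraction: float
    background_fraction: float
    enrichment_ratio: float
    p_value: float
    n_contexts: int
    n_excluded: int


def tcw_enrichment(catalog: VariantCatalog, genome: Genome,
                   window: ContextWindow = ContextWindow(),
                   classes: Sequence[str] = CYTOSINE_CLASSES) -> TcwEnrichment:
    """TCW motif enrichment of a catalog's C:G mutations over the genome background.

    The background is the TCW fraction among all genomic cytosines of the
    analyzed genome itself; the p-value is a one-sided exact binomial test of
    the observed TCW count against that background rate.
    """
    contexts, excluded = extract_contexts(genome, catalog, window, classes)
    if not contexts:
        raise ValueError("catalog has no eligible C:G SNV with a valid window")
    background = genome_tcw_background(genome)
    k = sum(is_tcw(c) for c in contexts)
    n = len(contexts)
    observed = k / n
    ratio = observed / background if background > 0 else float("inf")
    p = float(binomtest(k, n, background, alternative="greater").pvalue)
    return TcwEnrichment(observed, background, ratio, p, n, len(excluded))


def contexts_to_fasta(contexts: Iterable[OrientedContext], path) -> None:
    """Write oriented contexts as FASTA (the input format of logo renderers)."""
    with open(path, "w") as fh:
        for i, c in enumerate(contexts):
            v = c.source_variant
            fh.write(f">{i}|{v.chrom}:{v.pos + 1}{v.ref}>{v.alt}\n{c.sequence}\n")
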