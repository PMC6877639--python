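"""PAM-proximity analysis and intersection with predicted CRISPR off-target sites.

For every mutated cytosine the 6-base window at distances 15-20 downstream
(3' on the strand where the mutated base reads C) is tested for an NGG
protospacer-adjacent motif fully inside the window.  The observed hit
fraction is compared with the frequency among windows sampled uniformly from
the same genome — PAM-independence of the mutations shows as a fraction
comparable to that background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import Genome, OffTargetSite, Variant, VariantCatalog, revcomp


@dataclass(frozen=True)
class PamWindowSpec:
    """Inclusive 1-based downstream offsets of the scanned window (default 15..20)."""

    offset_start: int = 15
    offset_end: int = 20
    motif: str = "NGG"

    def __post_init__(self):
        if self.offset_start < 1 or self.offset_end < self.offset_start:
            raise ValueError("need 1 <= offset_start <= offset_end")

    @property
    def window_length(self) -> int:
        return self.offset_end - self.offset_start + 1


@dataclass(frozen=True)
class BackgroundSamplingSpec:
    """Uniform sampling of fixed-length windows genome-wide."""

    n_samples: int = 1_000_000
    window_length: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def contains_ngg(window: str) -> bool:
    """True iff an NGG trinucleotide lies fully within the 6-base window.

    Only the given strand is searched (start offsets 0..3); the
    reverse-strand CCN pattern is not counted.
    """
    if len(window) != 6:
        raise ValueError(f"window must be 6 bases, got {len(window)}")
    return any(window[i + 1:i + 3] == "GG" for i in range(4))


def _downstream_window(genome: Genome, variant: Variant,
                       spec: PamWindowSpec) -> str | None:
    """The +offset_start..+offset_end window 3' of the mutated C, or None.

    "Downstream" follows the strand on which the mutated base reads C: the
    plus strand for ref C, the minus strand (reverse complement, leftward on
    plus coordinates) for ref G.  None for off-chromosome windows.
    """
    length = genome.lengths[variant.chrom]
    if variant.ref == "C":
        start = variant.pos + spec.offset_start
        end = variant.pos + spec.offset_end + 1
        if end > length:
            return None
        return genome.fetch(variant.chrom, start, end)
    # ref G: downstream on the minus strand means lower plus-strand coordinates
    start = variant.pos - spec.offset_end
    end = variant.pos - spec.offset_start + 1
    if start < 0:
        return None
    return revcomp(genome.fetch(variant.chrom, start, end))


@dataclass(frozen=True)
class PamProximityResult:
    fraction: float
    n_evaluated: int
    n_excluded: int


def pam_proximity_fraction(catalog: VariantCatalog, genome: Genome,
                           spec: PamWindowSpec = PamWindowSpec(),
                           strand_mode: str = "mutated_c",
                           ) -> PamProximityResult:
    """Fraction of mutated cytosines with an NGG in their downstream window.

    Only SNVs at C:G reference sites are evaluated.  ``strand_mode`` selects
    the orientation rule: ``"mutated_c"`` (default) reads downstream 3' of
    the base as a C, ``"reference_plus"`` always reads the plus strand to the
    right.  Windows off the chromosome or containing N are excluded and
    counted.
    """
    if strand_mode not in ("mutated_c", "reference_plus"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    n_hit = n_eval = n_excl = 0
    for v in catalog:
        if not v.is_snv or v.ref not in ("C", "G"):
            continue
        if strand_mode == "mutated_c":
            window = _downstream_window(genome, v, spec)
        else:
            start, end = v.pos + spec.offset_start, v.pos + spec.offset_end + 1
            window = (genome.fetch(v.chrom, start, end)
                      if end <= genome.lengths[v.chrom] else None)
        if window is None or "N" in window:
            n_excl += 1
            continue
        n_eval += 1
        n_hit += contains_ngg(window)
    if n_eval == 0:
        raise ValueError("no evaluable C:G-site SNV in catalog")
    return PamProximityResult(n_hit / n_eval, n_eval, n_excl)


@dataclass(frozen=True)
class BackgroundPamResult:
    fraction: float
    se: float
    n_samples: int


def background_pam_frequency(genome: Genome,
                             spec: BackgroundSamplingSpec = BackgroundSamplingSpec(),
                             ) -> BackgroundPamResult:
    """NGG frequency among windows sampled uniformly over valid genome positions.

    Valid start positions are in-bounds and give an N-free window; positions
    are drawn with a seeded generator, uniformly across the concatenated
    valid positions of all chromosomes (long chromosomes weighted by length).
    Returns the hit fraction and its binomial standard error.
    """
    import re

    rng = np.random.default_rng(spec.seed)
    L = spec.window_length
    chroms = [name for name, n in genome.lengths.items() if n >= L]
    if not chroms:
        raise ValueError("no chromosome long enough for the window")
    if not any(re.search(f"[ACGT]{{{L}}}", genome.sequences[c]) for c in chroms):
        raise ValueError("no valid N-free window positions")
    counts = np.array([genome.lengths[c] - L + 1 for c in chroms], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1])

    # Rejection of N-containing draws keeps the distribution uniform over the
    # valid (N-free, in-bounds) start positions.
    hits = 0
    drawn = 0
    while drawn < spec.n_samples:
        m = spec.n_samples - drawn
        flat = rng.integers(0, total, size=m)
        idx = np.searchsorted(offsets, flat, side="right") - 1
        for ci, f in zip(idx, flat):
            start = int(f - offsets[ci])
            window = genome.sequences[chroms[ci]][start:start + L]
            if "N" in window:  # rejected: resampled on the next pass
                continue
            drawn += 1
            hits += contains_ngg(window)
    frac = hits / spec.n_samples
    se = float(np.sqrt(frac * (1 - frac) / spec.n_samples))
    return BackgroundPamResult(frac, se, spec.n_samples)


@dataclass(frozen=True)
class OffTargetIntersection:
    per_site: tuple[tuple[OffTargetSite, int], ...]  # descending CFD order
    total: int


def intersect_offtargets(catalog: VariantCatalog,
                         sites: Sequence[OffTargetSite],
                         flank: int = 0) -> OffTargetIntersection:
    """Count catalog variants falling in each predicted off-target interval.

    A variant hits a site iff the 0-based position of its first reference
    base lies in [start - flank, end + flank).  Sites are reported in
    descending CFD-score order with their hit counts plus the total.
    """
    by_chrom: dict[str, list[int]] = {}
    for v in catalog:
        by_chrom.setdefault(v.chrom, []).append(v.pos)
    for positions in by_chrom.values():
        positions.sort()
    ordered = sorted(sites, key=lambda s: -s.cfd_score)
    per_site = []
    total = 0
    for s in ordered:
        positions = by_chrom.get(s.chrom, [])
        lo = np.searchsorted(positions, s.start - flank, side="left")
        hi = np.searchsorted(positions, s.end + flank, side="left")
        n = int(hi - lo)
        per_site.append((s, n))
        total += n
    return OffTargetIntersection(tuple(per_site), total)
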