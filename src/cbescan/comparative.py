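"""Inter-clone comparisons: mutation-overlap matrix and chromosomal distribution.

Recurrence of the same mutation across independently derived clones would
indicate sequence-directed (rather than random) off-target activity; the
overlap matrix quantifies it.  The chromosome distribution summarizes where
each clone's C:G>T:A and C:G>G:C mutations fall, with mean +/- SD across
clones of a named group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import VariantCatalog
from .spectrum import classify_substitution

DEFAULT_DISTRIBUTION_CLASSES = ("C:G>T:A", "C:G>G:C")


@dataclass
class OverlapMatrix:
    """Symmetric shared-mutation counts; the diagonal holds catalog sizes."""

    clone_ids: tuple[str, ...]
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.clone_ids),
                            columns=list(self.clone_ids))


def overlap_matrix(catalogs: Sequence[VariantCatalog],
                   match_mode: str = "allele_aware") -> OverlapMatrix:
    """Pairwise shared-mutation counts between clone catalogs.

    A mutation is shared when two catalogs contain an identical
    (chrom, pos, ref, alt) entry (``allele_aware``, default) or an identical
    (chrom, pos) location (``position_only``).
    """
    if len(catalogs) < 2:
        raise ValueError("need at least two catalogs")
    ids = [c.clone_id for c in catalogs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate clone ids: {ids}")
    if match_mode == "allele_aware":
        keysets = [{(v.chrom, v.pos, v.ref, v.alt) for v in c} for c in catalogs]
    elif match_mode == "position_only":
        keysets = [{(v.chrom, v.pos) for v in c} for c in catalogs]
    else:
        raise ValueError(f"unknown match_mode {match_mode!r}")
    n = len(catalogs)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = len(catalogs[i])
        for j in range(i + 1, n):
            shared = len(keysets[i] & keysets[j])
            counts[i, j] = counts[j, i] = shared
    return OverlapMatrix(tuple(ids), counts)


@dataclass
class ChromDistribution:
    """Per-chromosome fraction of one clone's mutations in the counted classes."""

    clone_id: str
    fractions: dict[str, float]
    n_counted: int


@dataclass
class GroupDistribution:
    """Per-chromosome mean and sample SD across the clones of one group."""

    group_id: str
    clone_ids: tuple[str, ...]
    mean: dict[str, float]
    sd: dict[str, float | None]  # None when the group has a single clone


def chromosome_distribution(catalogs: Sequence[VariantCatalog],
                            grouping: Mapping[str, Sequence[str]],
                            chromosomes: Sequence[str] | None = None,
                            classes: Sequence[str] = DEFAULT_DISTRIBUTION_CLASSES,
                            min_total: int = 500,
                            ) -> tuple[list[ChromDistribution],
                                       list[GroupDistribution],
                                       list[str]]:
    """Chromosomal fractions of the selected mutation classes, with group stats.

    Clones whose total catalog size is <= ``min_total`` are excluded (and
    returned in the third element).  SD uses the sample (n-1) formula and is
    None for single-clone groups.
    """
    by_id = {c.clone_id: c for c in catalogs}
    if len(by_id) != len(catalogs):
        raise ValueError("duplicate clone ids")
    excluded = [c.clone_id for c in catalogs if len(c) <= min_total]
    eligible = {cid: c for cid, c in by_id.items() if len(c) > min_total}

    if chromosomes is None:
        chromosomes = sorted({v.chrom for c in eligible.values() for v in c})
    per_clone: dict[str, ChromDistribution] = {}
    for cid, cat in eligible.items():
        counts = {ch: 0 for ch in chromosomes}
        n = 0
        for v in cat:
            if not v.is_snv or v.ref not in ("C", "G"):
                continue
            if classify_substitution(v.ref, v.alt) not in classes:
                continue
            if v.chrom in counts:
                counts[v.chrom] += 1
                n += 1
        if n == 0:
            raise ValueError(f"clone {cid}: no mutations in classes {classes}")
        per_clone[cid] = ChromDistribution(
            cid, {ch: counts[ch] / n for ch in chromosomes}, n)

    groups = []
    for gid, members in grouping.items():
        present = [m for m in members if m in per_clone]
        if not present:
            raise ValueError(f"group {gid!r} empty after the >{min_total} filter")
        mean, sd = {}, {}
        for ch in chromosomes:
            vals = [per_clone[m].fractions[ch] for m in present]
            mean[ch] = sum(vals) / len(vals)
            if len(vals) >= 2:
                m = mean[ch]
                sd[ch] = math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))
            else:
                sd[ch] = None
        groups.append(GroupDistribution(gid, tuple(present), mean, sd))
    return list(per_clone.values()), groups, excluded


def distribution_table(per_clone: Sequence[ChromDistribution]) -> pd.DataFrame:
    chroms = list(per_clone[0].fractions) if per_clone else []
    rows = [[d.clone_id, d.n_counted] + [d.fractions[ch] for ch in chroms]
            for d in per_clone]
    return pd.DataFrame(rows, columns=["clone", "n_counted"] + chroms)
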