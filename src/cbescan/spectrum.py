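"""Mutation-spectrum classification and per-clone summaries.

Single-nucleotide substitutions are reported pyrimidine-normalized: each of
the 12 directed base changes maps onto one of six strand-invariant classes
(e.g. G>A is recorded as C:G>T:A).  Indels form a seventh class.  The module
also computes per-class fractions and fold changes of a clone's class counts
against the mean of designated control clones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import Variant, VariantCatalog

#: The six pyrimidine-normalized substitution classes, in conventional order.
SUBSTITUTION_CLASSES = (
    "C:G>T:A", "C:G>G:C", "C:G>A:T", "A:T>C:G", "A:T>G:C", "A:T>T:A")
INDEL_CLASS = "indel"
MUTATION_CLASSES = SUBSTITUTION_CLASSES + (INDEL_CLASS,)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_CLASS_BY_PAIR = {
    ("C", "T"): "C:G>T:A", ("G", "A"): "C:G>T:A",
    ("C", "G"): "C:G>G:C", ("G", "C"): "C:G>G:C",
    ("C", "A"): "C:G>A:T", ("G", "T"): "C:G>A:T",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
}

#: Control clones used by default when computing fold changes.
DEFAULT_CONTROL_CLONES = ("N1", "N2", "N3")


def classify_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-normalized class of a single-base substitution.

    Strand-complement invariant: ``classify(ref, alt) ==
    classify(complement(ref), complement(alt))``.
    """
    key = (ref.upper(), alt.upper())
    if key not in _CLASS_BY_PAIR:
        raise ValueError(f"not a valid substitution: {ref!r}>{alt!r}")
    return _CLASS_BY_PAIR[key]


@dataclass
class SpectrumSummary:
    """Per-clone mutation counts over the seven classes."""

    clone_id: str
    counts: dict[str, int]

    def __post_init__(self):
        full = {c: 0 for c in MUTATION_CLASSES}
        unknown = set(self.counts) - set(MUTATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown mutation class(es): {sorted(unknown)}")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("negative class count")
        full.update(self.counts)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class FoldChangeRecord:
    """A clone's count of one class relative to the control-clone mean."""

    clone_id: str
    mutation_class: str
    clone_count: int
    control_mean: float
    fold_change: float | None  # None when control_mean == 0

    @property
    def defined(self) -> bool:
        return self.fold_change is not None


def decompose_mnv(variant: Variant) -> list[Variant]:
    """Split a multi-nucleotide substitution into its per-base SNVs."""
    return [Variant(variant.chrom, variant.pos + i, r, a)
            for i, (r, a) in enumerate(zip(variant.ref, variant.alt)) if r != a]


def summarize_catalog(catalog: VariantCatalog) -> SpectrumSummary:
    """Count a catalog's variants into the seven mutation classes.

    Every variant is counted exactly once; indels count as one event each.
    Multi-nucleotide substitutions (equal-length ref/alt > 1) are decomposed
    into independent SNVs before counting.
    """
    counts = {c: 0 for c in MUTATION_CLASSES}
    for v in catalog:
        if v.kind == "SNV":
            counts[classify_substitution(v.ref, v.alt)] += 1
        elif v.kind == "MNV":
            for snv in decompose_mnv(v):
                counts[classify_substitution(snv.ref, snv.alt)] += 1
        else:
            counts[INDEL_CLASS] += 1
    return SpectrumSummary(catalog.clone_id, counts)


def type_fraction(summary: SpectrumSummary, mutation_class: str,
                  rounded: bool = False) -> float:
    """Percentage of the clone's mutations in one class (100 x count / total).

    With ``rounded=True`` the value is rounded half-up to one decimal, the
    precision used in printed spectrum tables.
    """
    if mutation_class not in MUTATION_CLASSES:
        raise ValueError(f"unknown mutation class {mutation_class!r}")
    if summary.total == 0:
        raise ValueError(f"clone {summary.clone_id}: empty summary (total 0)")
    pct = 100.0 * summary.counts[mutation_class] / summary.total
    if rounded:
        return math.floor(pct * 10 + 0.5) / 10
    return pct


def fold_changes(clone_summary: SpectrumSummary,
                 control_summaries: Sequence[SpectrumSummary],
                 classes: Iterable[str] = MUTATION_CLASSES,
                 ) -> list[FoldChangeRecord]:
    """Per-class fold change of a clone versus the mean of control clones.

    The fold change for a class is the clone's count divided by the
    arithmetic mean of the control clones' counts for that class; a zero
    control mean yields a flagged (None) fold change rather than infinity.
    """
    if not control_summaries:
        raise ValueError("need at least one control summary")
    records = []
    for cls in classes:
        mean = sum(s.counts[cls] for s in control_summaries) / len(control_summaries)
        count = clone_summary.counts[cls]
        fc = count / mean if mean > 0 else None
        records.append(FoldChangeRecord(clone_summary.clone_id, cls, count, mean, fc))
    return records


_TABLE_COLUMNS = ("clone", "total") + MUTATION_CLASSES


def spectrum_table(summaries: Sequence[SpectrumSummary]) -> pd.DataFrame:
    """One row per clone: total plus the seven class counts."""
    ids = [s.clone_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate clone_id in spectrum table")
    rows = [[s.clone_id, s.total] + [s.counts[c] for c in MUTATION_CLASSES]
            for s in summaries]
    return pd.DataFrame(rows, columns=list(_TABLE_COLUMNS))


def write_spectrum_table(summaries: Sequence[SpectrumSummary],
                         path) -> None:
    spectrum_table(summaries).to_csv(path, sep="\t", index=False)


def read_spectrum_table(path) -> list[SpectrumSummary]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        counts = {c: int(row[i + 2]) for i, c in enumerate(MUTATION_CLASSES)}
        s = SpectrumSummary(str(row.clone), counts)
        if s.total != int(row.total):
            raise ValueError(
                f"{path}: clone {row.clone} class counts sum to {s.total}, "
                f"total column says {row.total}")
        out.append(s)
    return out
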