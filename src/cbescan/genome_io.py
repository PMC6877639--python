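"""Data model and file I/O for genomes, variant catalogs, allele counts and off-target sites.

Coordinate conventions are fixed package-wide: all in-memory positions are
0-based (intervals half-open); external formats keep their native conventions
(VCF 1-based, BED-like off-target tables 0-based half-open).  Chromosome names
are matched by exact string comparison — no "chr" aliasing.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
VALID_SEQ_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class CoordinateError(ValueError):
    """A position or chromosome name does not exist in the attached genome."""


class Genome:
    """An in-memory reference genome: uppercase sequences keyed by chromosome.

    Lowercase (soft-masked) input is normalized to uppercase in the primary
    string; the masked intervals are retained in :attr:`softmask` as 0-based
    half-open runs per chromosome.
    """

    def __init__(self, sequences: Mapping[str, str],
                 softmask: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            up = seq.upper()
            bad = set(up) - VALID_SEQ_CHARS
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-nucleotide characters: {sorted(bad)}")
            if name in seqs:
                raise FormatError(f"duplicate chromosome name {name!r}")
            seqs[name] = up
        self.sequences = seqs
        self.softmask = {k: tuple(v) for k, v in (softmask or {}).items()}

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 0-based half-open interval [start, end).

        Raises :class:`CoordinateError` for an unknown chromosome or an
        out-of-bounds interval (no silent clipping).
        """
        if chrom not in self.sequences:
            raise CoordinateError(f"unknown chromosome {chrom!r} (exact-match lookup)")
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(
                f"interval [{start}, {end}) out of bounds for {chrom} (length {len(seq)})")
        return seq[start:end]


@dataclass(frozen=True, order=True)
class Variant:
    """One called mutation relative to the parental line, VCF-style anchored.

    ``pos`` is the 0-based position of the first reference base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - VALID_BASES:
                raise ValueError(f"{label} allele {allele!r} must be non-empty A/C/G/T")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.ref) < len(self.alt):
            return "insertion"
        if len(self.ref) > len(self.alt):
            return "deletion"
        return "MNV"

    @property
    def is_snv(self) -> bool:
        return self.kind == "SNV"

    def check_against(self, genome: Genome) -> bool:
        """True iff the ref allele matches the genome at (chrom, pos)."""
        return genome.fetch(self.chrom, self.pos, self.pos + len(self.ref)) == self.ref


class VariantCatalog:
    """One clone's mutations, unique and sorted by (chrom, pos, ref, alt)."""

    def __init__(self, clone_id: str, variants: Iterable[Variant] = (),
                 provenance: str = ""):
        self.clone_id = clone_id
        self.provenance = provenance
        self._variants: list[Variant] = sorted(set(variants))

    @property
    def variants(self) -> tuple[Variant, ...]:
        return tuple(self._variants)

    def add(self, variant: Variant) -> None:
        i = bisect.bisect_left(self._variants, variant)
        if i < len(self._variants) and self._variants[i] == variant:
            return
        self._variants.insert(i, variant)

    def __len__(self) -> int:
        return len(self._variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._variants)

    def __eq__(self, other) -> bool:
        return (isinstance(other, VariantCatalog)
                and self.clone_id == other.clone_id
                and self._variants == other._variants)

    def snvs(self) -> "VariantCatalog":
        return VariantCatalog(self.clone_id, (v for v in self if v.is_snv),
                              provenance=self.provenance)


@dataclass(frozen=True)
class PairedSiteCounts:
    """Clone ("tumor") vs parental ("normal") read support at one candidate site."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    tumor_ref_reads: int
    tumor_alt_reads: int
    normal_ref_reads: int
    normal_alt_reads: int

    def __post_init__(self):
        counts = (self.tumor_ref_reads, self.tumor_alt_reads,
                  self.normal_ref_reads, self.normal_alt_reads)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}: {counts}")

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref_reads + self.tumor_alt_reads

    @property
    def normal_depth(self) -> int:
        return self.normal_ref_reads + self.normal_alt_reads

    def to_variant(self) -> Variant:
        return Variant(self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class OffTargetSite:
    """A predicted CRISPR off-target locus (protospacer + PAM interval)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    grna_id: str
    mismatches: int
    cfd_score: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.mismatches < 0:
            raise ValueError("negative mismatch count")
        if not 0.0 <= self.cfd_score <= 1.0:
            raise ValueError(f"CFD score {self.cfd_score} outside [0, 1]")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> Genome:
    """Load a (multi-record) FASTA into a :class:`Genome`.

    Soft-masked (lowercase) stretches are recorded in ``genome.softmask`` and
    uppercased in the primary sequence.  Raises :class:`FormatError` for empty
    files, duplicate record names or non-ACGTN characters (naming the line).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    softmask: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate chromosome name {rec.id!r}")
        raw = str(rec.seq)
        bad = set(raw.upper()) - VALID_SEQ_CHARS
        if bad:
            lineno = _find_bad_line(path, bad)
            raise FormatError(
                f"{path}:{lineno}: invalid sequence character(s) {sorted(bad)} "
                f"in record {rec.id!r}")
        runs = _lowercase_runs(raw)
        if runs:
            softmask[rec.id] = runs
        sequences[rec.id] = raw.upper()
    return Genome(sequences, softmask)


def _find_bad_line(path: Path, bad: set[str]) -> int:
    badset = bad | {c.lower() for c in bad}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.startswith(">") and set(line.strip()) & badset:
                return i
    return 0


def _lowercase_runs(seq: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, c in enumerate(seq):
        if c.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, genome: Genome | None = None,
             clone_id: str | None = None) -> VariantCatalog:
    """Read a VCF 4.x into a catalog (positions converted to 0-based).

    Multi-allelic records are split into biallelic variants.  Records with
    symbolic or otherwise non-ACGT alleles are skipped; the number skipped is
    recorded in the catalog's ``provenance``.  With ``genome`` given, every
    ref allele is verified and mismatches raise :class:`CoordinateError`
    listing the offending records.  The clone id defaults to the ``clone=``
    tag in the header's source line (as written by :func:`write_vcf`), else
    the file stem.
    """
    import re

    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path))
    header_clone = re.search(r"^##source=cbescan clone=(\S+)", vcf.raw_header,
                             flags=re.M)
    variants: list[Variant] = []
    skipped = 0
    mismatches: list[str] = []
    for rec in vcf:
        ref = rec.REF.upper()
        if set(ref) - VALID_BASES:
            skipped += len(rec.ALT) or 1
            continue
        for alt in rec.ALT:
            alt = alt.upper()
            if not alt or set(alt) - VALID_BASES:
                skipped += 1
                continue
            v = Variant(rec.CHROM, rec.POS - 1, ref, alt)
            if genome is not None and not v.check_against(genome):
                mismatches.append(f"{rec.CHROM}:{rec.POS} {ref}>{alt}")
                continue
            variants.append(v)
    vcf.close()
    if mismatches:
        raise CoordinateError(
            "REF allele does not match genome for: " + ", ".join(mismatches))
    if clone_id is not None:
        cid = clone_id
    elif header_clone is not None:
        cid = header_clone.group(1)
    else:
        cid = path.stem
    prov = f"read from {path}"
    if skipped:
        prov += f" ({skipped} non-ACGT allele(s) skipped)"
    return VariantCatalog(cid, variants, provenance=prov)


def write_vcf(catalog: VariantCatalog, path: str | Path,
              genome: Genome | None = None) -> None:
    """Write a catalog as VCF 4.2 (1-based positions, contig headers if known)."""
    lines = ["##fileformat=VCFv4.2", f"##source=cbescan clone={catalog.clone_id}"]
    if genome is not None:
        for v in catalog:
            if v.chrom not in genome:
                raise CoordinateError(
                    f"variant chromosome {v.chrom!r} absent from genome")
        for name, length in genome.lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        for name in dict.fromkeys(v.chrom for v in catalog):
            lines.append(f"##contig=<ID={name}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in catalog:
        lines.append(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Allele-count and off-target tables

_COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "t_ref", "t_alt", "n_ref", "n_alt"]


def read_counts_table(path: str | Path,
                      indel_dialect: str = "vcf") -> list[PairedSiteCounts]:
    """Read a tab-delimited clone/parental allele-count table.

    Expected header columns: chrom, pos (1-based), ref, alt, t_ref, t_alt,
    n_ref, n_alt; '#'-comment lines allowed.  ``indel_dialect`` selects how
    indel alt alleles are encoded: ``"vcf"`` (anchored ref/alt strings) or
    ``"plusminus"`` (ref is the anchor base; alt ``+SEQ`` inserts SEQ after
    it, ``-SEQ`` deletes SEQ following it).
    """
    if indel_dialect not in ("vcf", "plusminus"):
        raise ValueError(f"unknown indel dialect {indel_dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if indel_dialect == "plusminus" and alt[0] in "+-":
            tail = alt[1:]
            ref, alt = (ref, ref + tail) if alt[0] == "+" else (ref + tail, ref)
        counts = (int(row.t_ref), int(row.t_alt), int(row.n_ref), int(row.n_alt))
        if any(c < 0 for c in counts):
            raise FormatError(f"{path}: negative read count at {row.chrom}:{row.pos}")
        out.append(PairedSiteCounts(str(row.chrom), int(row.pos) - 1, ref, alt, *counts))
    return out


def write_counts_table(sites: Sequence[PairedSiteCounts], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.pos + 1, s.ref_allele, s.alt_allele, s.tumor_ref_reads,
          s.tumor_alt_reads, s.normal_ref_reads, s.normal_alt_reads)
         for s in sites],
        columns=_COUNT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


_OFFTARGET_COLUMNS = ["chrom", "start", "end", "gRNA", "mismatches", "cfd"]


def read_offtarget_table(path: str | Path) -> list[OffTargetSite]:
    """Read a BED-compatible off-target site table, ordered by descending CFD."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in _OFFTARGET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    sites = [OffTargetSite(str(r.chrom), int(r.start), int(r.end), str(r.gRNA),
                           int(r.mismatches), float(r.cfd))
             for r in df.itertuples(index=False)]
    return sorted(sites, key=lambda s: -s.cfd_score)


def write_offtarget_table(sites: Sequence[OffTargetSite], path: str | Path) -> None:
    ordered = sorted(sites, key=lambda s: -s.cfd_score)
    df = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.grna_id, s.mismatches, s.cfd_score)
         for s in ordered],
        columns=_OFFTARGET_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
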