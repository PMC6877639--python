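"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the study design end-to-end: an i.i.d. reference
genome of configurable GC content, per-clone mutation catalogs mixing a
uniform background spectrum with an APOBEC-like component planted at TCW
cytosines (C>T and C>G on the strand where the deaminated base reads C), and
clone/parental ("tumor"/"normal") read counts at ~30-60x depth with clonal
heterozygous variants at expected allele fraction 0.5.  Truth records allow
parameter-recovery tests; every output is reproducible byte-for-byte under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import (Genome, PairedSiteCounts, Variant, VariantCatalog,
                        revcomp, write_counts_table, write_fasta, write_vcf)

BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of one simulated experiment.

    Defaults emulate a heavily edited clone: ~1000 somatic events of which
    90% carry the APOBEC TCW signature, mostly C>T, on a human-like (41% GC)
    1 Mb genome sequenced at 40x with clonal heterozygous variants.
    """

    genome_length: int = 1_000_000
    gc_content: float = 0.41
    n_chromosomes: int = 2
    n_background_mutations: int = 100
    n_apobec_mutations: int = 900
    apobec_ct_fraction: float = 0.85
    n_indels: int = 20
    clone_count: int = 1
    expected_vaf: float = 0.5
    mean_depth: float = 40.0
    sequencing_error_rate: float = 0.001
    n_decoy_sites: int = 200
    seed: int = 0

    def __post_init__(self):
        for name in ("genome_length", "n_chromosomes", "n_background_mutations",
                     "n_apobec_mutations", "n_indels", "clone_count",
                     "n_decoy_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gc_content", "apobec_ct_fraction", "expected_vaf",
                     "sequencing_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Provenance of one planted variant."""

    variant: Variant
    origin: str  # "background" | "apobec" | "indel"
    context_at_planting: str  # oriented trinucleotide, "." if unavailable


def _rng(config: SimulationConfig, rng: np.random.Generator | None):
    return rng if rng is not None else np.random.default_rng(config.seed)


def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> Genome:
    """i.i.d. genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if config.genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    rng = _rng(config, rng)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    per = config.genome_length // config.n_chromosomes
    sizes = [per] * config.n_chromosomes
    sizes[-1] += config.genome_length - per * config.n_chromosomes
    sequences = {}
    for i, n in enumerate(sizes, 1):
        draw = rng.choice(4, size=n, p=probs)
        sequences[f"chr{i}"] = "".join(BASES[draw])
    return Genome(sequences)


def tcw_site_positions(genome: Genome) -> list[tuple[str, int, str]]:
    """All TCW cytosines: (chrom, 0-based C position, strand '+'/'-').

    '+' sites read T-C-[A/T] on the plus strand; '-' sites are plus-strand
    guanines reading [T/A]-G-A, i.e. TCW on the minus strand.
    """
    sites = []
    for chrom, seq in genome.sequences.items():
        for m in re.finditer(r"(?=TC[AT])", seq):
            sites.append((chrom, m.start() + 1, "+"))
        for m in re.finditer(r"(?=[TA]GA)", seq):
            sites.append((chrom, m.start() + 1, "-"))
    return sites


def _oriented_trinuc(seq: str, pos: int) -> str:
    if pos < 1 or pos + 2 > len(seq):
        return "."
    tri = seq[pos - 1:pos + 2]
    return tri if seq[pos] in ("C", "T") else revcomp(tri)


def plant_mutations(genome: Genome, config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[list[VariantCatalog], list[TruthRecord]]:
    """Plant per-clone catalogs: APOBEC events at TCW sites plus uniform background.

    APOBEC SNVs sit at TCW cytosines (either strand) and are C>T with
    probability ``apobec_ct_fraction``, else C>G, expressed on the strand
    where the mutated base reads C.  Background SNVs are uniform over
    positions with the alt drawn uniformly from the three non-reference
    bases.  Indels are 1-3 bp insertions or deletions, VCF-anchored.
    Positions are drawn without replacement within each clone.
    """
    rng = _rng(config, rng)
    tcw = tcw_site_positions(genome)
    if len(tcw) < config.n_apobec_mutations:
        raise ValueError(
            f"genome has {len(tcw)} TCW sites, need {config.n_apobec_mutations}")
    chroms = list(genome.sequences)
    lengths = genome.lengths
    catalogs, truths = [], []
    for k in range(config.clone_count):
        used: set[tuple[str, int]] = set()
        variants: list[Variant] = []
        clone_truth: list[TruthRecord] = []

        idx = rng.choice(len(tcw), size=config.n_apobec_mutations, replace=False)
        for i in idx:
            chrom, pos, strand = tcw[int(i)]
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            seq = genome.sequences[chrom]
            to_t = rng.random() < config.apobec_ct_fraction
            if strand == "+":
                ref, alt = "C", ("T" if to_t else "G")
            else:  # C>T on minus strand is G>A on plus
                ref, alt = "G", ("A" if to_t else "C")
            v = Variant(chrom, pos, ref, alt)
            tri = seq[pos - 1:pos + 2] if strand == "+" else revcomp(seq[pos - 1:pos + 2])
            variants.append(v)
            clone_truth.append(TruthRecord(v, "apobec", tri))

        placed = 0
        while placed < config.n_background_mutations:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(lengths[chrom]))
            if (chrom, pos) in used:
                continue
            ref = genome.sequences[chrom][pos]
            if ref == "N":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            used.add((chrom, pos))
            v = Variant(chrom, pos, ref, alt)
            variants.append(v)
            clone_truth.append(TruthRecord(
                v, "background", _oriented_trinuc(genome.sequences[chrom], pos)))
            placed += 1

        placed = 0
        while placed < config.n_indels:
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = int(rng.integers(1, 4))
            pos = int(rng.integers(lengths[chrom] - size - 1))
            if (chrom, pos) in used:
                continue
            seq = genome.sequences[chrom]
            if rng.random() < 0.5:  # insertion after the anchor base
                anchor = seq[pos]
                ins = "".join(BASES[rng.integers(0, 4, size=size)])
                ref, alt = anchor, anchor + ins
            else:  # deletion of `size` bases after the anchor
                ref, alt = seq[pos:pos + 1 + size], seq[pos]
            if "N" in ref:
                continue
            used.add((chrom, pos))
            v = Variant(chrom, pos, ref, alt)
            variants.append(v)
            clone_truth.append(TruthRecord(v, "indel", "."))
            placed += 1

        catalogs.append(VariantCatalog(
            f"sim{k + 1}", variants,
            provenance=f"synthetic (seed {config.seed}, clone {k + 1})"))
        truths.extend(clone_truth)
    return catalogs, truths


def simulate_counts(genome: Genome, catalog: VariantCatalog,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[list[PairedSiteCounts], list[PairedSiteCounts]]:
    """Clone/parental read counts at every planted site, plus decoy sites.

    At a planted site, depth is Poisson(mean_depth) in each sample (floored
    at 1); clone alt reads are Binomial(depth, vaf') with vaf' the expected
    VAF perturbed by the error rate, parental alt reads Binomial(depth,
    error_rate).  Decoys are non-mutant positions with error-only alt reads
    in both samples.  Returns (planted_counts, decoy_counts).
    """
    rng = _rng(config, rng)
    e = config.sequencing_error_rate
    vaf_eff = config.expected_vaf * (1 - e) + (1 - config.expected_vaf) * e / 3

    def depths() -> tuple[int, int]:
        t = max(1, int(rng.poisson(config.mean_depth)))
        n = max(1, int(rng.poisson(config.mean_depth)))
        return t, n

    planted = []
    occupied = set()
    for v in catalog:
        occupied.add((v.chrom, v.pos))
        t_depth, n_depth = depths()
        t_alt = int(rng.binomial(t_depth, vaf_eff))
        n_alt = int(rng.binomial(n_depth, e))
        planted.append(PairedSiteCounts(
            v.chrom, v.pos, v.ref, v.alt,
            t_depth - t_alt, t_alt, n_depth - n_alt, n_alt))

    decoys = []
    chroms = list(genome.sequences)
    lengths = genome.lengths
    while len(decoys) < config.n_decoy_sites:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(lengths[chrom]))
        if (chrom, pos) in occupied:
            continue
        ref = genome.sequences[chrom][pos]
        if ref == "N":
            continue
        occupied.add((chrom, pos))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        t_depth, n_depth = depths()
        t_alt = int(rng.binomial(t_depth, e))
        n_alt = int(rng.binomial(n_depth, e))
        decoys.append(PairedSiteCounts(
            chrom, pos, ref, alt, t_depth - t_alt, t_alt, n_depth - n_alt, n_alt))
    return planted, decoys


@dataclass
class SimulationBundle:
    config: SimulationConfig
    genome: Genome
    catalogs: list[VariantCatalog]
    truth: list[TruthRecord]
    counts: dict[str, tuple[list[PairedSiteCounts], list[PairedSiteCounts]]]


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Run the whole generator on a single seeded random stream."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    catalogs, truth = plant_mutations(genome, config, rng)
    counts = {c.clone_id: simulate_counts(genome, c, config, rng)
              for c in catalogs}
    return SimulationBundle(config, genome, catalogs, truth, counts)


def write_bundle(bundle: SimulationBundle, outdir: str | Path) -> dict:
    """Write FASTA, per-clone truth VCFs, count TSVs and a parameter manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / "genome.fa")
    files = {"genome": "genome.fa"}
    for cat in bundle.catalogs:
        write_vcf(cat, outdir / f"{cat.clone_id}.truth.vcf", bundle.genome)
        planted, decoys = bundle.counts[cat.clone_id]
        write_counts_table(planted + decoys, outdir / f"{cat.clone_id}.counts.tsv")
        files[cat.clone_id] = f"{cat.clone_id}.truth.vcf"
    manifest = {
        "parameters": dataclasses.asdict(bundle.config),
        "files": files,
        "n_truth_records": len(bundle.truth),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
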