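# Methods

## Overview and model

`cbescan` analyzes whole-genome variant calls from single-cell-derived
clones edited with an APOBEC-based cytosine base editor, compared against
the unedited parental line. The underlying model of off-target CBE activity
has three observable components, each with its own module:

1. **Somatic origin.** A genuine clone-specific mutation is clonal and
   heterozygous, so its variant allele fraction (VAF) in the clone is ~0.5
   and ~0 in the parental sample. The evidence at a site is a 2×2 table of
   alt/ref read counts in clone ("tumor") and parent ("normal"); the
   one-sided Fisher exact test asks whether the clone is enriched for the
   alt allele.
2. **Deaminase signature.** APOBEC deamination acts on cytosines in TCW
   trinucleotides, producing C→T (and, via abasic-site processing, C→G)
   changes. On the genome this appears on either strand, so all context
   analysis first re-orients every C:G-site variant onto the strand where
   the mutated base reads C.
3. **Guide independence.** If mutagenesis were Cas9/gRNA-directed, mutated
   positions would be PAM-proximal and concentrated at predicted
   off-target loci. The PAM-window statistic and the off-target
   intersection test both nulls.

## Somatic filter

The retention rule is four strict inequalities applied jointly:
`p < max_p` (default 0.001), `normal_vaf < max_normal_vaf` (default 0.05),
`tumor_vaf > min_tumor_vaf` (default 1/3), and
`tumor_alt_reads > min_tumor_alt_reads` (default 6). Notes:

* The Fisher test is one-sided for alt-allele gain in the clone, matching
  somatic-calling intent; a two-sided alternative is available via the
  `alternative` argument. The p-value is computed by
  `scipy.stats.fisher_exact`, and the test suite verifies it against
  brute-force hypergeometric tail enumeration for every 2×2 table with
  total ≤ 60 (tolerance 1e-12).
* The clone-VAF threshold "33.33 %" is interpreted as the exact fraction
  1/3; the literal decimal 0.3333 is exported as an alternative constant.
  At a site with VAF exactly 1/3 (e.g. 20/60) both interpretations reject,
  since the comparison is strict; sites between 0.3333 and 1/3 are
  astronomically rare at realistic depths.
* Sites with no alt reads in the clone evaluate to p = 1 and are rejected
  by the VAF/read-support rules rather than skipped, keeping the filter a
  total function; every rejection records all failed criteria.

## Spectrum accounting

Substitutions are reported pyrimidine-normalized (G→A counts as C:G>T:A),
making classes strand-invariant; indels form a seventh class. Equal-length
multi-base substitutions are decomposed into independent per-base SNVs
before counting. Percentages are rounded half-up to one decimal when a
display value is requested; unrounded values are always available (one
published fraction, 1573/1813 = 86.76 %, rounds to 86.8 % although it is
conventionally quoted as 86.7 % — the package reports the computed value).
Fold changes divide a clone's class count by the arithmetic mean of the
control clones' counts (default controls: N1, N2, N3); a zero control mean
yields a flagged record, never infinity.

## Context and TCW statistics

Context extraction reads `upstream` bases 5′ and `downstream` bases 3′ of
the mutated base on the strand where it is a C (reverse complement for
reference-G sites). The default window is −5..+25, the range used for
published deaminase logos; windows crossing a chromosome end or containing
N are excluded and counted, never padded, because padding would bias column
frequencies. Information content per column is `2 − H` bits with
`H = −Σ f·log₂ f` over observed bases; the small-sample correction
`e(n) = 3/(2·ln 2·n)` is available but off by default since realistic
context sets here number in the hundreds to thousands. The C:G>G:C logo is
produced only for clones with more than 40 such transversions (configurable
`cg_logo_min_count`), below which a logo is noise.

TCW enrichment compares the fraction of oriented contexts with T at −1 and
A/T at +1 against the analyzed genome's own TCW background — the fraction
of all genomic cytosines (both strands) in TCW trinucleotide context — so
synthetic genomes are self-consistent and no canned human constant enters.
The p-value is a one-sided exact binomial test of the observed TCW count at
the background rate.

## PAM-window statistic

For each mutated cytosine, the 6 bases at distances 15–20 downstream are
scanned for an NGG fully inside the window (start offsets 0–3). "Downstream"
is 3′ on the strand where the mutated base reads C, consistent with the
deamination-strand orientation used for contexts; a `reference_plus` mode
exists for sensitivity analysis. Only the oriented strand is searched — the
reverse-strand CCN representation is deliberately not counted. The
background samples `n_samples` (default 10⁶) window start positions
uniformly over all valid (in-bounds, N-free) positions genome-wide with a
seeded generator, using rejection of N-containing draws, which preserves
uniformity over the valid set; the returned standard error is binomial.

## Off-target intersection and comparison

A variant hits a predicted off-target interval iff the 0-based position of
its first reference base lies in `[start − flank, end + flank)`; results
are reported per site in descending CFD-score order. The overlap matrix
counts identical `(chrom, pos, ref, alt)` entries by default
(`allele_aware`); a `position_only` mode counts shared locations, exposing
the looser published phrasing rather than silently choosing one. The
chromosome distribution uses clones with more than 500 total mutations
(configurable), restricted to the C:G>T:A and C:G>G:C classes, with sample
(n−1) SD per group and `None` flagged for single-clone groups. Sex
chromosomes are not special-cased; in male-derived lines haploid calls
there simply pass the VAF filter more easily, which is a property of the
data, not the statistic.

## Synthetic data generator

The generator emulates the study conditions: i.i.d. genome (default 1 Mb,
41 % GC — the human genome-wide value — over 2 chromosomes), ~1000 planted
events per clone of which 900 are APOBEC-type at TCW cytosines (85 % C→T,
15 % C→G, expressed on the deaminated strand), 100 uniform-background SNVs
(position uniform, alt uniform over the three non-reference bases, so each
C:G class has probability gc/3 and each A:T class (1−gc)/3), and 20 short
(1–3 bp) indels. Read evidence is Poisson(40) depth per sample — the
middle of the 30–60× design range — with clone alt reads
Binomial(depth, VAF′), VAF′ = 0.5 perturbed by the default 0.1 % per-base
error rate, parental alt reads Binomial(depth, error), plus 200 decoy
(non-mutant) sites with error-only evidence in both samples. All draws come
from a single `numpy` Generator seeded from the config, making every output
byte-reproducible.

What the generator does **not** emulate: alignment and mapping artifacts,
strand bias, copy-number variation, subclonal structure, GC-dependent
coverage, CpG depletion and repeat structure of real genomes. Passing
recovery tests therefore demonstrates correctness of the statistical
pipeline under its stated model, not robustness to real-sequencing
artifacts; on real data the upstream caller's additional filters matter.
One visible consequence: on an i.i.d. 41 %-GC genome the NGG background is
≈0.14, whereas the real human genome — with its dinucleotide structure —
gives ≈0.19; the pipeline's PAM comparison is always against the analyzed
genome's own background, so the null logic is unaffected.

## Numerical and interface choices

* Internal coordinates are 0-based half-open everywhere; VCF stays 1-based
  and BED-like tables 0-based at the file boundary. Chromosome names match
  exactly (no "chr" aliasing): a mismatch is a hard error, since silent
  aliasing hides data bugs.
* Indels are VCF-anchored; a `+SEQ`/`−SEQ` count-table dialect is accepted
  behind a flag because supplementary mutation tables in this field use
  both conventions.
* Catalogs are kept sorted and duplicate-free by construction; filtering is
  order-invariant.
* Degenerate inputs error early and loudly: empty FASTA, zero-depth sites,
  empty eligible context sets, all-N genomes.
* Problem sizes in the test and acceptance runs (200 kb–1 Mb genomes,
  10⁵–10⁶ background samples, ~1000 planted events, Fisher sweep to table
  total 60) were chosen as the smallest scales at which every statistical
  assertion retains clear power (binomial CIs a few SE wide, exhaustive
  sweeps still exact).

## Known limitations

* The hg38-dependent observables (the 0.188 genome-wide NGG background and
  per-clone PAM-proximity fractions of real clones) require the reference
  genome and the published per-clone mutation lists; the corresponding test
  runs only when those files are placed under `data/external/`.
* The somatic filter implements exactly the four published criteria; it
  does not reproduce a caller's auxiliary strand-bias or homopolymer
  filters, so on real pileups it is expected to be slightly more permissive
  than the original pipeline.
* Functional annotation (exonic/non-synonymous classification) is out of
  scope; it requires a gene-model database.
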