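# cbescan

Genome-wide off-target mutation analysis for cytosine-base-edited cell
clones.

Cytosine base editors (CBEs) couple a catalytically impaired Cas9 to an
APOBEC-family cytidine deaminase and convert C:G pairs to T:A without
double-strand breaks. Because the deaminase remains active off its guide
target, edited clones can accumulate genome-wide mutations that carry the
APOBEC mutagenesis signature: C→T transitions and C→G transversions
concentrated at TCW trinucleotides (T at −1, W = A or T at +1 of the
mutated C). `cbescan` is for researchers evaluating editor specificity from
whole-genome sequencing of edited clones against their parental line. It
implements:

* **somatic filtering** — clone ("tumor") vs parental ("normal") allele
  counts tested with a one-sided Fisher exact test on
  `[[t_alt, t_ref], [n_alt, n_ref]]`, retained iff `p < 0.001`,
  normal VAF `< 5%`, clone VAF `> 1/3`, and clone alt reads `> 6`
  (all strict);
* **mutation spectra** — pyrimidine-normalized classification into the six
  substitution classes (C:G>T:A, C:G>G:C, C:G>A:T, A:T>C:G, A:T>G:C,
  A:T>T:A) plus indels, per-class fractions and fold changes against
  control clones;
* **context signatures** — strand-normalized flanking sequence around
  mutated cytosines, position frequency matrices with information content
  `2 − H` bits per position (sequence-logo math), and TCW-motif enrichment
  with an exact binomial test against the genome's own TCW background;
* **PAM proximity** — the NGG frequency in the 6-base window 15–20 bases
  downstream (3′ on the strand where the mutated base reads C) of every
  mutated cytosine, compared with windows sampled uniformly from the same
  genome;
* **off-target intersection** — variant counts over predicted CRISPR
  off-target intervals ranked by CFD score;
* **inter-clone comparison** — shared-mutation overlap matrices and
  per-chromosome mutation distributions with group mean ± SD;
* **synthetic data** — a seeded generator producing a reference genome,
  clone catalogs with a planted APOBEC component at TCW sites, and paired
  clone/parental read counts, with full truth records for
  parameter-recovery testing.

## Worked example

Simulate an edited clone and push it through the whole pipeline:

```sh
cbescan simulate --seed 3 --genome-length 200000 \
    --n-apobec 900 --n-background 100 --out demo
cbescan filter --counts demo/sim1.counts.tsv --clone-id sim1 \
    --out demo/sim1.somatic.vcf
cbescan signature --vcf demo/sim1.somatic.vcf --genome demo/genome.fa \
    --out demo/tcw.json
cbescan pamscan --vcf demo/sim1.somatic.vcf --genome demo/genome.fa \
    --out demo/pam.json --background-samples 200000 --seed 3
```

which prints:

```
1005/1220 sites retained
TCW observed=0.973 background=0.173 ratio=5.61 p=0
observed=0.120 background=0.144
```

Reading: of 1220 candidate sites (1020 planted mutations + 200 decoys),
1005 pass the four-threshold somatic filter — 98.5 % of the planted
variants and none of the decoys. Among the retained C:G-class mutations,
97.3 % sit in a TCW context against a genomic background of 17.3 %, a
5.6-fold enrichment — the APOBEC signature the generator planted. The PAM
window statistic (0.120) is comparable to the genome-wide sampled
background (0.144), i.e. the mutations are not PAM-proximal.

The same stages run end-to-end from a YAML config with
`cbescan run --config config.yaml --out results/`, emitting per-stage
TSV/JSON artifacts and a checksummed manifest.

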