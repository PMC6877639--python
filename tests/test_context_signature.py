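"""Context extraction, sequence-logo math, and TCW-motif statistics."""

import numpy as np
import pytest

from cbescan.context_signature import (ContextWindow, ExcludedContext,
                                       OrientedContext, build_context_matrix,
                                       extract_context, extract_contexts,
                                       genome_tcw_background, is_tcw,
                                       small_sample_correction, tcw_enrichment,
                                       tcw_fraction)
from cbescan.genome_io import Genome, Variant, VariantCatalog, revcomp
from cbescan.synthetic import SimulationConfig, simulate


class TestExtractContext:
    def test_plus_strand_read(self):
        g = Genome({"chr1": "AATCAGG"})
        ctx = extract_context(g, Variant("chr1", 3, "C", "T"), ContextWindow(1, 1))
        assert isinstance(ctx, OrientedContext)
        assert ctx.sequence == "TCA"
        assert ctx.center_index == 1

    def test_minus_strand_is_reverse_complement(self):
        # "CCTGAT" with a G>A at index 3 reads TCA once flipped to the strand
        # where the mutated base is a C (mirror of the plus-strand example).
        g = Genome({"chr1": "CCTGAT"})
        ctx = extract_context(g, Variant("chr1", 3, "G", "A"), ContextWindow(1, 1))
        assert ctx.sequence == "TCA"

    def test_asymmetric_window_orientation(self):
        g = Genome({"chr1": "AATCAGGT"})
        ctx = extract_context(g, Variant("chr1", 3, "C", "T"), ContextWindow(1, 3))
        assert ctx.sequence == "TCAGG"
        # The G on the other strand at the complementary position sees the
        # same oriented window when upstream/downstream are swapped in space.
        g2 = Genome({"chr1": revcomp("AATCAGGT")})
        ctx2 = extract_context(g2, Variant("chr1", 4, "G", "A"), ContextWindow(1, 3))
        assert ctx2.sequence == "TCAGG"

    def test_chromosome_edge_is_excluded(self):
        g = Genome({"chr1": "CAAAAAAAAA"})
        res = extract_context(g, Variant("chr1", 0, "C", "T"), ContextWindow(1, 1))
        assert isinstance(res, ExcludedContext)
        assert res.reason == "out_of_bounds"

    def test_n_window_is_excluded(self):
        g = Genome({"chr1": "ANTCAGG"})
        res = extract_context(g, Variant("chr1", 3, "C", "T"), ContextWindow(3, 1))
        assert isinstance(res, ExcludedContext)
        assert res.reason == "contains_N"

    def test_non_cg_snv_rejected(self):
        g = Genome({"chr1": "AATCAGG"})
        with pytest.raises(ValueError):
            extract_context(g, Variant("chr1", 0, "A", "T"), ContextWindow(1, 1))

    def test_class_selection(self, tiny_genome):
        cat = VariantCatalog("x", [Variant("chr1", 3, "C", "T"),
                                   Variant("chr1", 13, "C", "G"),
                                   Variant("chr1", 8, "A", "T")])
        kept, excluded = extract_contexts(tiny_genome, cat, ContextWindow(2, 2),
                                          classes=("C:G>T:A",))
        assert [c.source_variant.pos for c in kept] == [3]


class TestContextMatrix:
    def test_identical_contexts_are_fully_conserved(self):
        m = build_context_matrix(["TCA"] * 7, center_index=1)
        assert np.allclose(m.info_bits, 2.0)
        assert np.allclose(m.freq.sum(axis=1), 1.0)
        # all mass on T, C, A respectively
        assert m.freq[0, 3] == 1.0 and m.freq[1, 1] == 1.0 and m.freq[2, 0] == 1.0

    def test_uniform_position_has_zero_information(self):
        m = build_context_matrix(["ACA", "CCA", "GCA", "TCA"], center_index=1)
        assert m.info_bits[0] == pytest.approx(0.0, abs=1e-12)
        assert m.info_bits[1] == pytest.approx(2.0)

    def test_two_base_split_gives_one_bit(self):
        # Position +1 split 2 T / 2 A: H = 1, so 2 - H = 1 bit.
        m = build_context_matrix(["TCT", "TCT", "TCA", "TCA"], center_index=1)
        assert m.info_bits[2] == pytest.approx(1.0)

    def test_positions_centered_on_mutated_c(self):
        m = build_context_matrix(["TCAGG"], center_index=1)
        assert list(m.positions) == [-1, 0, 1, 2, 3]

    def test_small_sample_correction_subtracts_en(self):
        n = 4
        m0 = build_context_matrix(["TCA"] * n, center_index=1)
        m1 = build_context_matrix(["TCA"] * n, correction="small_sample",
                                  center_index=1)
        assert np.allclose(m1.info_bits, m0.info_bits - small_sample_correction(n))
        # floored at zero for maximally entropic columns
        m2 = build_context_matrix(["ACA", "CCA", "GCA", "TCA"],
                                  correction="small_sample", center_index=1)
        assert m2.info_bits[0] == 0.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            build_context_matrix(["TCA", "TCAA"], center_index=1)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            build_context_matrix([])


class TestTcwFraction:
    def test_all_tcw(self):
        assert tcw_fraction(["TCA", "TCT"], center_index=1) == 1.0

    def test_none_tcw(self):
        assert tcw_fraction(["ACG"], center_index=1) == 0.0

    def test_window_too_small_is_an_error(self):
        with pytest.raises(ValueError):
            is_tcw("CA", center_index=0)

    def test_planted_fraction_recovered(self):
        # 700 APOBEC + 300 background mutations planted (n=1000, fixed seed):
        # using the planted labels as oracle, every APOBEC context is TCW and
        # the background contexts hit TCW at the genome rate, so the observed
        # TCW count minus the APOBEC count must fall inside the exact
        # binomial 99% CI of (n_background_contexts, background_rate).
        from scipy.stats import binom
        config = SimulationConfig(genome_length=150_000, n_apobec_mutations=700,
                                  n_background_mutations=300, n_indels=0,
                                  n_decoy_sites=0, seed=5)
        bundle = simulate(config)
        truth = {(t.variant.chrom, t.variant.pos): t.origin for t in bundle.truth}
        contexts, _ = extract_contexts(bundle.genome, bundle.catalogs[0],
                                       ContextWindow(1, 1))
        n_apobec = sum(truth[(c.source_variant.chrom, c.source_variant.pos)]
                       == "apobec" for c in contexts)
        n_bg = len(contexts) - n_apobec
        k = sum(is_tcw(c) for c in contexts)
        assert n_apobec == 700  # every planted APOBEC event is a C:G-class SNV
        bg_rate = genome_tcw_background(bundle.genome)
        lo = binom.ppf(0.005, n_bg, bg_rate)
        hi = binom.ppf(0.995, n_bg, bg_rate)
        assert lo <= k - n_apobec <= hi


class TestTcwEnrichment:
    def test_saturated_background(self):
        # Every cytosine with full context sits in TCW; no guanines at all.
        g = Genome({"chr1": "TCA" * 40})
        cat = VariantCatalog("x", [Variant("chr1", 4, "C", "T")])
        res = tcw_enrichment(cat, g, ContextWindow(1, 1))
        assert res.background_fraction == 1.0
        assert res.observed_fraction == 1.0
        assert res.enrichment_ratio == 1.0

    def test_zero_observed_gives_ratio_zero_p_one(self):
        g = Genome({"chr1": "TCA" * 30 + "GCG" + "TCA" * 30})
        cat = VariantCatalog("x", [Variant("chr1", 91, "C", "T")])  # GCG center
        res = tcw_enrichment(cat, g, ContextWindow(1, 1))
        assert res.observed_fraction == 0.0
        assert res.enrichment_ratio == 0.0
        assert res.p_value == 1.0

    def test_background_matches_bruteforce_scan(self, random_genome):
        # Exhaustive per-position oracle over a <=1 kb genome.
        seq = random_genome.sequences["chrR"]
        num = den = 0
        for i in range(1, len(seq) - 1):
            if seq[i] == "C":
                den += 1
                num += seq[i - 1] == "T" and seq[i + 1] in "AT"
            elif seq[i] == "G":
                den += 1
                num += seq[i + 1] == "A" and seq[i - 1] in "TA"
        assert genome_tcw_background(random_genome) == pytest.approx(num / den)

    def test_no_eligible_variant_is_an_error(self, tiny_genome):
        with pytest.raises(ValueError):
            tcw_enrichment(VariantCatalog("e"), tiny_genome)


class TestStrandSymmetry:
    def test_revcomp_genome_preserves_contexts_and_tcw(self, random_genome):
        # Reverse-complementing the genome and re-representing each variant
        # on the new plus strand must leave the oriented contexts, the TCW
        # fraction and the context matrix unchanged.
        seq = random_genome.sequences["chrR"]
        L = len(seq)
        rng = np.random.default_rng(7)
        cg = [i for i in range(5, L - 5) if seq[i] in "CG"]
        picks = rng.choice(len(cg), size=40, replace=False)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        fwd, rev = [], []
        for j in picks:
            i = cg[int(j)]
            ref = seq[i]
            alt = "T" if ref == "C" else "A"
            fwd.append(Variant("chrR", i, ref, alt))
            rev.append(Variant("chrR", L - 1 - i, comp[ref], comp[alt]))
        g_rev = Genome({"chrR": revcomp(seq)})
        w = ContextWindow(3, 5)
        ctx_f, _ = extract_contexts(random_genome, VariantCatalog("f", fwd), w)
        ctx_r, _ = extract_contexts(g_rev, VariantCatalog("r", rev), w)
        assert sorted(c.sequence for c in ctx_f) == sorted(c.sequence for c in ctx_r)
        assert tcw_fraction(ctx_f) == tcw_fraction(ctx_r)
        assert genome_tcw_background(g_rev) == pytest.approx(
            genome_tcw_background(random_genome))
        mf = build_context_matrix(sorted(c.sequence for c in ctx_f), center_index=3)
        mr = build_context_matrix(sorted(c.sequence for c in ctx_r), center_index=3)
        assert np.allclose(mf.freq, mr.freq)
        assert np.allclose(mf.info_bits, mr.info_bits)
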