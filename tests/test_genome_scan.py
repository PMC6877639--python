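"""PAM-window scanning, background sampling, off-target intersection."""

import itertools

import numpy as np
import pytest

from cbescan.genome_io import (Genome, OffTargetSite, Variant, VariantCatalog,
                               revcomp)
from cbescan.genome_scan import (BackgroundSamplingSpec, PamWindowSpec,
                                 background_pam_frequency, contains_ngg,
                                 intersect_offtargets, pam_proximity_fraction)


def oracle_ngg(window: str) -> bool:
    """Independent NGG check: GG anywhere in the last five bases."""
    return "GG" in window[1:]


class TestContainsNgg:
    def test_hit_inside_window(self):
        assert contains_ngg("TAGGAC") is True

    def test_no_gg_anywhere(self):
        assert contains_ngg("ACACAC") is False

    def test_gg_at_final_positions_counts(self):
        # NGG start offset 3 uses bases 4-5; GG there must count.
        assert contains_ngg("ACACGG") is True

    def test_wrong_length_is_an_error(self):
        with pytest.raises(ValueError):
            contains_ngg("ACGTA")

    def test_all_4096_hexamers_match_enumeration(self):
        hits = impl = 0
        for w in itertools.product("ACGT", repeat=6):
            w = "".join(w)
            hits += oracle_ngg(w)
            impl += contains_ngg(w)
            assert contains_ngg(w) == oracle_ngg(w), w
        assert impl == hits


class TestPamProximity:
    def test_single_variant_with_pam_window(self):
        # Mutated C at index 0; bases 15..20 downstream are "TAGGAC".
        seq = "C" + "A" * 14 + "TAGGAC" + "A" * 10
        g = Genome({"chr1": seq})
        cat = VariantCatalog("x", [Variant("chr1", 0, "C", "T")])
        res = pam_proximity_fraction(cat, g)
        assert res.fraction == 1.0 and res.n_evaluated == 1

    def test_minus_strand_window_is_reverse_complement(self):
        # A mutated G reads C on the minus strand; its downstream window is
        # the reverse complement of the 6 plus-strand bases to its LEFT.
        left = revcomp("TAGGAC")
        seq = "A" * 10 + left + "A" * 14 + "G" + "A" * 5
        g = Genome({"chr1": seq})
        pos = 10 + 6 + 14
        assert seq[pos] == "G"
        cat = VariantCatalog("x", [Variant("chr1", pos, "G", "A")])
        res = pam_proximity_fraction(cat, g)
        assert res.fraction == 1.0

    def test_at_only_genome_has_no_pam(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(["A", "T"])[rng.integers(0, 2, 400)])
        seq = seq[:50] + "C" + seq[51:]
        g = Genome({"chr1": seq})
        cat = VariantCatalog("x", [Variant("chr1", 50, "C", "T")])
        assert pam_proximity_fraction(cat, g).fraction == 0.0

    def test_out_of_bounds_window_excluded(self):
        g = Genome({"chr1": "C" + "A" * 10})
        cat = VariantCatalog("x", [Variant("chr1", 0, "C", "T")])
        with pytest.raises(ValueError):  # the only site is excluded
            pam_proximity_fraction(cat, g)

    def test_matches_bruteforce_on_small_genome(self, random_genome):
        seq = random_genome.sequences["chrR"]
        variants = [Variant("chrR", i, seq[i], "T" if seq[i] == "C" else "A")
                    for i in range(len(seq)) if seq[i] in "CG"]
        cat = VariantCatalog("x", variants)
        res = pam_proximity_fraction(cat, random_genome)
        hits = n = 0
        for v in variants:  # position-by-position oracle
            if v.ref == "C":
                w = seq[v.pos + 15:v.pos + 21]
            else:
                w = revcomp(seq[v.pos - 20:v.pos - 14]) if v.pos >= 20 else ""
            if len(w) == 6:
                n += 1
                hits += oracle_ngg(w)
        assert res.n_evaluated == n
        assert res.fraction == pytest.approx(hits / n)

    def test_strand_symmetry_under_genome_revcomp(self, random_genome):
        seq = random_genome.sequences["chrR"]
        L = len(seq)
        comp = {"C": "G", "G": "C"}
        variants = [Variant("chrR", i, seq[i], "T" if seq[i] == "C" else "A")
                    for i in range(25, L - 25) if seq[i] in "CG"]
        mirrored = [Variant("chrR", L - 1 - v.pos, comp[v.ref],
                            "A" if comp[v.ref] == "G" else "T")
                    for v in variants]
        g_rev = Genome({"chrR": revcomp(seq)})
        a = pam_proximity_fraction(VariantCatalog("f", variants), random_genome)
        b = pam_proximity_fraction(VariantCatalog("r", mirrored), g_rev)
        assert a.fraction == pytest.approx(b.fraction)
        assert a.n_evaluated == b.n_evaluated

    def test_reference_plus_mode(self):
        seq = "G" + "A" * 14 + "TAGGAC" + "A" * 10
        g = Genome({"chr1": seq})
        cat = VariantCatalog("x", [Variant("chr1", 0, "G", "A")])
        # mutated-C orientation looks left (out of bounds); plus orientation
        # looks right and finds the PAM.
        plus = pam_proximity_fraction(cat, g, strand_mode="reference_plus")
        assert plus.fraction == 1.0
        with pytest.raises(ValueError):
            pam_proximity_fraction(cat, g, strand_mode="mutated_c")


class TestBackgroundPam:
    def test_all_a_genome_has_zero_frequency(self):
        g = Genome({"chr1": "A" * 2000})
        res = background_pam_frequency(g, BackgroundSamplingSpec(5000, seed=1))
        assert res.fraction == 0.0

    def test_reproducible_under_seed(self, random_genome):
        spec = BackgroundSamplingSpec(20_000, seed=42)
        r1 = background_pam_frequency(random_genome, spec)
        r2 = background_pam_frequency(random_genome, spec)
        assert r1 == r2

    def test_sampled_matches_exhaustive_scan(self):
        # Uniform-composition genome: the sampled frequency must sit within
        # 3 SE of the exhaustive all-windows value.
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        g = Genome({"chr1": seq})
        exact = np.mean([contains_ngg(seq[i:i + 6])
                         for i in range(len(seq) - 5)])
        res = background_pam_frequency(g, BackgroundSamplingSpec(50_000, seed=2))
        assert abs(res.fraction - exact) <= 3 * res.se

    def test_n_windows_rejected(self):
        # All-N genome: no valid window anywhere.
        g = Genome({"chr1": "N" * 2000})
        with pytest.raises(ValueError):
            background_pam_frequency(g, BackgroundSamplingSpec(100, seed=0))

    def test_n_gaps_are_resampled_not_scored(self):
        # Half the genome is N; sampling must still return n_samples draws,
        # all from the N-free half.
        g = Genome({"chr1": "N" * 1000 + "G" * 1000})
        res = background_pam_frequency(g, BackgroundSamplingSpec(2000, seed=3))
        assert res.n_samples == 2000
        assert res.fraction == 1.0  # every valid window is GGGGGG


class TestIntersectOfftargets:
    def test_variant_inside_interval(self):
        cat = VariantCatalog("x", [Variant("chr1", 100, "C", "T")])
        sites = [OffTargetSite("chr1", 90, 113, "HEK3", 1, 0.8)]
        res = intersect_offtargets(cat, sites)
        assert res.total == 1
        assert res.per_site[0][1] == 1

    def test_half_open_boundaries(self):
        sites = [OffTargetSite("chr1", 90, 113, "HEK3", 1, 0.8)]
        at_start = VariantCatalog("s", [Variant("chr1", 90, "C", "T")])
        at_end = VariantCatalog("e", [Variant("chr1", 113, "C", "T")])
        assert intersect_offtargets(at_start, sites).total == 1
        assert intersect_offtargets(at_end, sites).total == 0

    def test_empty_site_list(self):
        cat = VariantCatalog("x", [Variant("chr1", 100, "C", "T")])
        assert intersect_offtargets(cat, []).total == 0

    def test_flank_extends_interval(self):
        cat = VariantCatalog("x", [Variant("chr1", 88, "C", "T")])
        sites = [OffTargetSite("chr1", 90, 113, "HEK3", 1, 0.8)]
        assert intersect_offtargets(cat, sites).total == 0
        assert intersect_offtargets(cat, sites, flank=2).total == 1

    def test_matches_quadratic_bruteforce(self):
        rng = np.random.default_rng(12)
        variants = [Variant(f"chr{rng.integers(1, 4)}", int(p), "C", "T")
                    for p in rng.integers(0, 500, size=80)]
        cat = VariantCatalog("x", set(variants))
        sites = [OffTargetSite(f"chr{rng.integers(1, 4)}", int(s), int(s) + 23,
                               "HEK3", int(rng.integers(0, 5)),
                               float(rng.random()))
                 for s in rng.integers(0, 500, size=40)]
        res = intersect_offtargets(cat, sites)
        brute = {id(s): sum(1 for v in cat
                            if v.chrom == s.chrom and s.start <= v.pos < s.end)
                 for s in sites}
        assert res.total == sum(brute.values())
        for site, n in res.per_site:
            assert n == brute[id(site)]
        # output ordered by descending CFD
        cfds = [s.cfd_score for s, _ in res.per_site]
        assert cfds == sorted(cfds, reverse=True)
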