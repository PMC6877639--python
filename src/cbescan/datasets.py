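"""Published per-clone mutation spectra used as validation inputs.

These are the reported whole-genome spectrum summaries for iPSC clones
derived with (or without) cytosine-base-editor exposure: six
pyrimidine-normalized substitution counts plus indels per clone.  Clones
N1/N2/N3 are the procedure controls (GFP-plasmid transfection only); for
those, only the C:G>T:A counts are recorded here, which is all the
fold-change baseline needs.
"""

from __future__ import annotations

from .spectrum import SpectrumSummary

# clone -> (C:G>T:A, C:G>G:C, C:G>A:T, A:T>C:G, A:T>G:C, A:T>T:A, indel)
_CLONE_SPECTRA: dict[str, tuple[int, ...]] = {
    "ANC-1": (254, 63, 175, 48, 206, 57, 66),
    "ANC-2": (241, 69, 169, 38, 214, 43, 73),
    "AN21-1": (5612, 718, 371, 167, 817, 98, 113),
    "AN21-2": (3597, 399, 275, 40, 185, 46, 63),
    "HK34": (2086, 59, 71, 10, 23, 6, 45),
    "RF23M": (437, 41, 69, 5, 9, 12, 26),
    "RF24M": (1573, 96, 76, 13, 15, 7, 33),
}

#: Reported totals (six classes + indels) for the clones above.
PUBLISHED_TOTALS = {
    "ANC-1": 869, "ANC-2": 847, "AN21-1": 7896, "AN21-2": 4605,
    "HK34": 2300, "RF23M": 599, "RF24M": 1813,
}

#: C:G>T:A counts of the three procedure-control clones (fold-change baseline).
CONTROL_CGTA_COUNTS = {"N1": 46, "N2": 42, "N3": 39}

_CLASS_ORDER = ("C:G>T:A", "C:G>G:C", "C:G>A:T",
                "A:T>C:G", "A:T>G:C", "A:T>T:A", "indel")


def load_published_spectra() -> dict[str, SpectrumSummary]:
    """The cleanly tabulated clone spectra as :class:`SpectrumSummary` objects."""
    return {clone: SpectrumSummary(clone, dict(zip(_CLASS_ORDER, counts)))
            for clone, counts in _CLONE_SPECTRA.items()}


def control_spectra_cgta_only() -> list[SpectrumSummary]:
    """Control-clone summaries carrying only their C:G>T:A counts."""
    return [SpectrumSummary(cid, {"C:G>T:A": n})
            for cid, n in CONTROL_CGTA_COUNTS.items()]


#: One representative (ref, alt) per mutation class; indels as an insertion.
_CLASS_REPRESENTATIVE = {
    "C:G>T:A": ("C", "T"), "C:G>G:C": ("C", "G"), "C:G>A:T": ("C", "A"),
    "A:T>C:G": ("A", "C"), "A:T>G:C": ("A", "G"), "A:T>T:A": ("A", "T"),
    "indel": ("C", "CA"),
}


def spectrum_to_catalog(summary: SpectrumSummary,
                        chrom: str = "chrS") -> "VariantCatalog":
    """A synthetic catalog whose spectrum realizes ``summary`` exactly.

    Variants are placed at consecutive positions on one synthetic chromosome
    with a fixed representative substitution per class; useful for verifying
    the counting path against tabulated per-clone spectra.
    """
    from .genome_io import Variant, VariantCatalog

    variants = []
    pos = 0
    for cls in _CLASS_ORDER:
        ref, alt = _CLASS_REPRESENTATIVE[cls]
        for _ in range(summary.counts[cls]):
            variants.append(Variant(chrom, pos, ref, alt))
            pos += 2
    return VariantCatalog(summary.clone_id, variants,
                          provenance="synthetic realization of a spectrum")
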