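import numpy as np
import pytest

from cbescan.genome_io import Genome, Variant, VariantCatalog
from cbescan.synthetic import SimulationConfig, simulate


@pytest.fixture
def tiny_genome() -> Genome:
    # chr1 carries the worked context-extraction examples; chr2 is filler.
    return Genome({"chr1": "AATCAGGTACGTTCATTTAGGACTGCAT",
                   "chr2": "CCTGATCCTGATCCTGAT"})


@pytest.fixture
def random_genome() -> Genome:
    rng = np.random.default_rng(11)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=800)])
    return Genome({"chrR": seq})


@pytest.fixture(scope="session")
def sim_bundle():
    """A mid-sized seeded simulation shared across tests (read-only)."""
    config = SimulationConfig(genome_length=200_000, n_apobec_mutations=900,
                              n_background_mutations=100, n_indels=20,
                              n_decoy_sites=200, seed=3)
    return simulate(config)


def make_catalog(clone_id: str, triples) -> VariantCatalog:
    """Catalog from (chrom, pos, ref, alt) tuples."""
    return VariantCatalog(clone_id, (Variant(*t) for t in triples))
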