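import numpy as np
import pytest

import mitotrace as mt


@pytest.fixture(scope="session")
def tiny_genes():
    """Two-gene toy alignment: 4 specimens, widths 6 and 9."""
    g1 = mt.GeneAlignment(
        "nad2",
        ["S1", "S2", "S3", "S4"],
        ["ATGAGA", "ATGAGA", "ATGGGA", "ATGAGA"],
    )
    g2 = mt.GeneAlignment(
        "nad4",
        ["S1", "S2", "S3", "S4"],
        ["CTAATGATG", "TTAATGATG", "CTAATGATG", "CTAATGATG"],
    )
    return [g1, g2]


@pytest.fixture(scope="session")
def small_population():
    """Default-condition synthetic population, fixed seed."""
    config = mt.SimConfig(seed=1234)
    return mt.simulate_population(config)


@pytest.fixture(scope="session")
def small_pipeline(small_population):
    """Masked matrix, haplotype table and distances for the population."""
    alignments, meta, truth = small_population
    concat = mt.concatenate(alignments)
    masked = mt.mask_columns(concat)
    table = mt.collapse_haplotypes(masked)
    dm = mt.pairwise_distances(table)
    return masked, table, dm, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(99)
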