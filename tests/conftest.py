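import numpy as np
import pandas as pd
import pytest

from polyqtlseq.simulate import CrossConfig, simulate_counts


def counts(rows):
    """Build an allele-count DataFrame from (chrom, pos, ref, alt, depth, alt_depth) rows."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_depth"])


@pytest.fixture(scope="session")
def small_cross():
    """A small planted-QTL tetraploid cross: 4 x 2 Mb genome, causal on chr03."""
    config = CrossConfig(
        n_chromosomes=4,
        chrom_length_bp=2_000_000,
        n_p2_simplex=600,
        n_p1_simplex=600,
        n_duplex=150,
        n_spurious=60,
        causal=("chr03", 1_100_000),
        n_progeny=60,
        bulk_size=20,
        seed=42,
    )
    tables, truth = simulate_counts(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def null_cross():
    """Null cross: no causal locus, bulks assigned at random."""
    config = CrossConfig(
        n_chromosomes=4,
        chrom_length_bp=2_000_000,
        n_p2_simplex=800,
        n_p1_simplex=0,
        n_duplex=0,
        n_spurious=0,
        causal=None,
        n_progeny=60,
        bulk_size=20,
        seed=7,
    )
    tables, truth = simulate_counts(config, rule="random")
    return config, tables, truth
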