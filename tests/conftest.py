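import math

import numpy as np
import pytest

from chromisd import FixtureSpec, GenomeGrid, RPParams, generate
from chromisd.grid import GeneAnnotation


@pytest.fixture
def small_grid():
    return GenomeGrid(("chr1", "chr2"), (10_000, 5_500), window_size=1000)


@pytest.fixture(scope="session")
def tiny_spec():
    # small geometry: full pipeline in well under a second
    return FixtureSpec(
        n_chroms=2,
        chrom_length=1_000_000,
        n_genes=120,
        n_profiles=6,
        n_informative=2,
        n_cistromes=8,
        n_query=25,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_fixture(tiny_spec):
    return generate(tiny_spec)


def oracle_chrom_rp(values, gene: GeneAnnotation, grid: GenomeGrid, params: RPParams):
    """Brute-force per-window RP: explicit loop, weight evaluated inline."""
    total = 0.0
    off = grid.offset_index[gene.chrom]
    for w in range(grid.windows_in(gene.chrom)):
        _, start, end = grid.window_bounds(off + w)
        mid = (start + end) / 2.0
        if gene.tss - params.L <= mid <= gene.tss + params.L:
            d = abs(mid - gene.tss) / params.L
            x = math.exp(-params.mu * d)
            total += 2.0 * x / (1.0 + x) * values[off + w]
    return total
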