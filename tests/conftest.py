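import numpy as np
import pandas as pd
import pytest

from pleiosim.fixtures import FixtureSpec, LDBlock, make_fixture
from pleiosim.marker_io import MAP_COLUMNS, GenotypeMatrix


def toy_map(n, chrom="1", alleles=None):
    """Marker map for hand-built toy matrices; +1 allele sorts second."""
    rows = []
    for j in range(n):
        a, b = alleles[j] if alleles else ("A", "G")
        rows.append([f"m{j + 1}", chrom, 1000 * (j + 1), a, b, max(a, b), np.nan])
    return pd.DataFrame(rows, columns=MAP_COLUMNS)


@pytest.fixture
def toy_geno():
    """3 individuals x 2 polymorphic markers, no missing calls."""
    values = np.array([[-1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return GenotypeMatrix(values, toy_map(2), ["i1", "i2", "i3"])


@pytest.fixture(scope="session")
def panel():
    """Inbred diversity-panel fixture without LD blocks (session-cached)."""
    return make_fixture(FixtureSpec(n_individuals=200, n_markers=600, seed=11))


@pytest.fixture(scope="session")
def ld_panel():
    """Panel with pronounced LD blocks for spurious-pleiotropy selection."""
    blocks = tuple(LDBlock(20, 0.6) for _ in range(12))
    return make_fixture(FixtureSpec(n_individuals=300, n_markers=1000,
                                    ld_blocks=blocks, seed=12))


@pytest.fixture(scope="session")
def outbred_panel():
    """Panel with heterozygotes so dominance/epistasis are non-trivial."""
    return make_fixture(FixtureSpec(n_individuals=200, n_markers=400,
                                    inbred_fraction=0.0, seed=13))
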