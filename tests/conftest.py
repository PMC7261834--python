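import numpy as np
import pytest

from ssrdem.io_formats import GenotypeMatrix, Partition
from ssrdem.synthetic import worldwide_preset


@pytest.fixture(scope="session")
def preset():
    """The worldwide panel preset (shared across tests; treat as read-only)."""
    g, geo, true_q, clusters = worldwide_preset(1)
    return dict(g=g, geo=geo, true_q=true_q, clusters=clusters)


@pytest.fixture
def two_fixed_clusters():
    """Two groups fixed for disjoint alleles at every locus: maximal
    differentiation, trivially separable."""
    n_per, L = 30, 10
    calls = np.zeros((2 * n_per, L, 2), dtype=np.int64)
    calls[:n_per] = 11
    calls[n_per:] = 22
    g = GenotypeMatrix(
        tuple(f"i{i:03d}" for i in range(2 * n_per)),
        tuple(f"l{l}" for l in range(L)),
        calls,
    )
    p = Partition({f"i{i:03d}": ("A" if i < n_per else "B") for i in range(2 * n_per)})
    return g, p


def random_matrix(rng, n=20, L=5, n_alleles=4, missing_rate=0.0, base=101):
    calls = rng.integers(base, base + n_alleles, size=(n, L, 2))
    if missing_rate:
        drop = rng.random((n, L)) < missing_rate
        calls[drop] = -1
    return GenotypeMatrix(
        tuple(f"i{i:03d}" for i in range(n)),
        tuple(f"l{l}" for l in range(L)),
        calls,
    )
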