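import numpy as np
import pytest

from lfapy import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genotypes():
    """A 2 x 3 genotype matrix used in the I/O round-trip examples."""
    return GenotypeMatrix(
        np.array([[0, 1, 2], [2, 2, 0]], dtype=np.int8),
        snp_ids=["rs1", "rs2"],
        sample_ids=["s1", "s2", "s3"],
    )


def random_genotype_matrix(rng, m, n, missing_rate=0.0):
    vals = rng.integers(0, 3, size=(m, n)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((m, n)) < missing_rate
        vals[mask] = -1
    return GenotypeMatrix(vals)
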