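import numpy as np
import pytest

from cassava_mgwas.types import (
    GenotypeMatrix,
    MetaboliteMatrix,
    PopulationLabels,
    SnpRecord,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_genotypes(rng, n_samples=10, n_snps=20, missing_rate=0.0, chrom="Chr1"):
    calls = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = -1
    positions = np.sort(rng.choice(np.arange(1, 10 * n_snps + 1), n_snps, replace=False))
    snps = [SnpRecord(chrom, int(p)) for p in positions]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, snps, calls)


@pytest.fixture
def toy_genotypes(rng):
    return random_genotypes(rng, n_samples=10, n_snps=20, missing_rate=0.1)


@pytest.fixture
def toy_metabolites(rng):
    n, m, r = 8, 5, 2
    vals = rng.gamma(5.0, 100.0, size=(n, m, r))
    return MetaboliteMatrix(
        [f"s{i:03d}" for i in range(n)], [f"M{j}" for j in range(m)], vals
    )


@pytest.fixture
def two_pop_labels():
    return PopulationLabels(
        {f"s{i:03d}": ("cultivated" if i < 5 else "wild") for i in range(10)}
    )
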