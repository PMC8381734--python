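import numpy as np
import pandas as pd
import pytest

from vqtlkit import GenotypeMatrix
from vqtlkit.dataio import VARIANT_COLUMNS


def make_genotypes(calls: np.ndarray, chrom: str = "1",
                   spacing: int = 1000) -> GenotypeMatrix:
    """Wrap a raw dosage matrix in a GenotypeMatrix with synthetic ids."""
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    variants = pd.DataFrame(
        [(chrom, 1 + j * spacing, f"v{j}", "A", "G") for j in range(m)],
        columns=VARIANT_COLUMNS)
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_genotypes(rng):
    """50 samples x 20 common SNPs with a sprinkle of missing calls."""
    calls = rng.integers(0, 3, size=(50, 20)).astype(np.int16)
    miss = rng.random(calls.shape) < 0.03
    calls[miss] = -1
    return make_genotypes(calls)
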