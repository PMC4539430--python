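import numpy as np
import pandas as pd
import pytest

from qtsmap import GeneticMap, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_genotypes(X: np.ndarray, spacing_cm: float = 50.0, chrom: str = "1") -> GenotypeMatrix:
    """Wrap a coded array as a GenotypeMatrix with widely spaced markers."""
    n, p = X.shape
    markers = pd.DataFrame(
        {
            "marker": [f"m{j}" for j in range(p)],
            "chrom": chrom,
            "pos_cm": np.arange(p) * spacing_cm,
            "allele_high": "A",
            "allele_low": "B",
        }
    )
    return GenotypeMatrix(
        [f"L{k}" for k in range(n)], markers, X, max_het_fraction=1.0, max_missing_fraction=1.0
    )


@pytest.fixture
def balanced_genotypes(rng):
    """60 lines x 8 unlinked markers, exactly balanced +/-1 per marker."""
    n, p = 60, 8
    X = np.ones((n, p))
    for j in range(p):
        idx = rng.permutation(n)[: n // 2]
        X[idx, j] = -1.0
    return make_genotypes(X)


@pytest.fixture
def small_map():
    return GeneticMap.uniform(n_chromosomes=2, markers_per_chromosome=30, spacing_cm=1.0)
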