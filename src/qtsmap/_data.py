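"""Coercion helpers between plain arrays and the domain containers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PhenotypeTable


def as_genotype_matrix(X) -> GenotypeMatrix:
    """Accept a GenotypeMatrix or a coded (n_lines, n_markers) array."""
    if isinstance(X, GenotypeMatrix):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("genotypes must be a 2-D lines x markers array")
    n, p = X.shape
    markers = pd.DataFrame(
        {
            "marker": [f"m{j + 1}" for j in range(p)],
            "chrom": "0",
            "pos_cm": np.arange(p, dtype=float),
            "allele_high": "A",
            "allele_low": "B",
        }
    )
    return GenotypeMatrix(
        [f"L{k + 1}" for k in range(n)], markers, X, max_het_fraction=1.0, max_missing_fraction=1.0
    )


def as_phenotype_table(y, G: GenotypeMatrix) -> PhenotypeTable:
    """Accept a PhenotypeTable or an (n_lines,) / (n_lines, n_env) array.

    Arrays are assumed row-aligned with ``G.line_ids``; tables are reordered
    to that alignment.
    """
    if isinstance(y, PhenotypeTable):
        vals = y.aligned_to(G.line_ids)
        return PhenotypeTable(G.line_ids, y.env_ids, vals)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != G.n_lines:
        raise ValueError("phenotype rows must match the number of genotype lines")
    env = [f"E{h + 1}" for h in range(y.shape[1])]
    return PhenotypeTable(G.line_ids, env, y)
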