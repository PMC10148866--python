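"""Expression normalization: log2 transform followed by quantile
normalization across samples, the standard guard against library-size and
batch effects before rank-based tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix

__all__ = ["quantile_normalize", "normalize_expression"]


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize rows (samples) to a common reference distribution.

    The reference is the across-sample mean of sorted value vectors; ties
    within a sample receive the average of the reference values at the tied
    ranks.  Afterwards every sample shares the identical sorted value
    multiset, and the map is idempotent.
    """
    arr = values.to_numpy(dtype=float)
    if arr.size == 0:
        return values.copy()
    reference = np.sort(arr, axis=1).mean(axis=0)
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        row = arr[i]
        order = np.argsort(row, kind="stable")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference values over tied observations
        uniq, inverse = np.unique(row, return_inverse=True)
        if uniq.size < row.size:
            sums = np.bincount(inverse, weights=ranked)
            counts = np.bincount(inverse)
            ranked = (sums / counts)[inverse]
        out[i] = ranked
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_expression(
    raw_counts: pd.DataFrame, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(count + pseudocount) then quantile normalization across samples.

    ``raw_counts`` is samples x genes with non-negative entries.
    """
    arr = raw_counts.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw counts must be non-negative")
    logged = pd.DataFrame(
        np.log2(arr + pseudocount), index=raw_counts.index, columns=raw_counts.columns
    )
    return ExpressionMatrix(quantile_normalize(logged), normalized=True)
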