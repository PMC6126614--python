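"""Median-of-ratios size factors and count normalization.

For each sample j the size factor is the median over reference genes of
K_ij / (prod_j K_ij)^(1/n), the reference set being all genes with strictly
positive counts in every sample. Factors are deliberately not rescaled to
geometric mean one: only ratios of size factors matter downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_fixtures import CountMatrix

__all__ = ["size_factors_median_ratio", "normalize_counts"]


def size_factors_median_ratio(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, one positive factor per sample."""
    k = counts.counts.astype(float)
    ref_mask = (k > 0).all(axis=1)
    if not ref_mask.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter genes or "
            "supply a pseudo-reference before computing size factors"
        )
    logs = np.log(k[ref_mask])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(sf, index=counts.samples, name="size_factor")


def normalize_counts(counts: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    missing = [s for s in counts.samples if s not in sf.index]
    if missing:
        raise KeyError(f"size factors missing for samples: {missing}")
    factors = sf.loc[counts.samples].to_numpy(dtype=float)
    if not np.isfinite(factors).all() or (factors <= 0).any():
        raise ValueError("size factors must be positive and finite")
    return pd.DataFrame(
        counts.counts / factors[np.newaxis, :],
        index=counts.gene_ids,
        columns=counts.samples,
    )
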