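"""Median-of-ratios size-factor normalization and log2 transform.

Raw RNA-seq counts are not comparable across libraries because sequencing
depth varies.  The median-of-ratios estimator (the DESeq family default)
computes, for each library, the median ratio of its counts to a per-gene
pseudo-reference (the geometric mean of that gene across libraries),
restricted to genes with no zero count.  Dividing by these size factors and
taking log2 (after adding a pseudocount) yields expression values on the
scale used by the downstream self-organizing map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "MedianRatioNormalizer",
    "compute_size_factors",
    "normalize_log2",
]


class MedianRatioNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios normalizer with log2 output.

    Follows the scikit-learn convention that rows are observations: here one
    row is one sequencing library and the columns are genes (the transpose of
    the usual genes x samples count table; the module-level helpers accept
    the genes x samples orientation directly).

    Parameters
    ----------
    pseudocount : float, default=1.0
        Added to the size-factor-scaled counts before log2.  Must be positive
        whenever zero counts are present.
    log : bool, default=True
        If False, ``transform`` returns size-factor-scaled counts without the
        log2 step.

    Attributes
    ----------
    log_geomeans_ : ndarray of shape (n_genes,)
        Natural-log geometric mean of each gene across the fitted libraries;
        ``-inf`` for genes outside the reference set.
    reference_mask_ : ndarray of bool, shape (n_genes,)
        Genes with a strictly positive count in every fitted library.  Only
        these contribute to the median of ratios.
    size_factors_ : ndarray of shape (n_libraries,)
        Size factor of each library seen during ``fit``.
    """

    def __init__(self, pseudocount: float = 1.0, log: bool = True):
        self.pseudocount = pseudocount
        self.log = log

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64, ensure_min_samples=2)
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        with np.errstate(divide="ignore"):
            logs = np.log(X)
        self.reference_mask_ = np.all(X > 0, axis=0)
        if not self.reference_mask_.any():
            raise ValueError(
                "median-of-ratios reference set is empty: no gene has a "
                "positive count in every library; filter all-zero-containing "
                "genes or supply a matrix with at least one such gene"
            )
        self.log_geomeans_ = np.where(
            self.reference_mask_, logs.mean(axis=0), -np.inf
        )
        self.n_features_in_ = X.shape[1]
        self.size_factors_ = self._factors(X)
        return self

    def _factors(self, X: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            logs = np.log(X)
        log_ratios = logs[:, self.reference_mask_] - self.log_geomeans_[self.reference_mask_]
        return np.median(np.exp(log_ratios), axis=1)

    def size_factors(self, X) -> np.ndarray:
        """Size factors of libraries ``X`` against the fitted reference."""
        check_is_fitted(self)
        X = check_array(X, dtype=np.float64, ensure_min_samples=1)
        return self._factors(X)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X, dtype=np.float64, ensure_min_samples=1)
        factors = self._factors(X)
        scaled = X / factors[:, None]
        if not self.log:
            return scaled
        if self.pseudocount <= 0 and np.any(scaled == 0):
            raise ValueError("zero counts require a positive pseudocount")
        return np.log2(scaled + self.pseudocount)


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for a genes x samples count table.

    For sample *j* the factor is the median over reference genes *g* of
    ``count[g, j] / geomean_g`` where ``geomean_g`` is the geometric mean of
    gene *g* across all samples and the reference set is the genes with a
    positive count everywhere.  Factors are not rescaled afterwards.
    """
    norm = MedianRatioNormalizer().fit(counts.T.to_numpy())
    return pd.Series(norm.size_factors_, index=counts.columns, name="size_factor")


def normalize_log2(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), genes x samples.

    ``factors`` defaults to :func:`compute_size_factors` of ``counts``.
    """
    if factors is None:
        factors = compute_size_factors(counts)
    factors = pd.Series(factors).reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    scaled = counts.to_numpy(dtype=np.float64) / factors.to_numpy()[None, :]
    if pseudocount <= 0 and np.any(scaled == 0):
        raise ValueError("zero counts require a positive pseudocount")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    return pd.DataFrame(
        np.log2(scaled + pseudocount), index=counts.index, columns=counts.columns
    )
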