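"""Expression filtering, log transformation and quantile normalization.

Two equivalent surfaces are provided. The scikit-learn transformers
(:class:`ExpressedGeneFilter`, :class:`Log2FpkmTransform`,
:class:`QuantileNormalizer`) follow the sklearn convention of
``(n_samples, n_features)`` input, compose with ``sklearn.pipeline`` and
carry fitted state with trailing-underscore attributes. The module-level
functions (:func:`filter_expressed`, :func:`log_transform`,
:func:`quantile_normalize`) are thin wrappers over the same kernels that
operate on the field-standard gene x sample ``DataFrame`` orientation.

Processing order follows the usual convention for FPKM input: the
expression filter is applied on the raw FPKM scale first ("greater than 1"
is strict), values are then transformed to log2(FPKM+1), and finally the
samples are quantile-normalized (classic sort--average--reassign; ties
within a sample receive the mean of the reference values at the tied
ranks). Missing values are rejected, never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import EmptyResultError

__all__ = [
    "filter_expressed",
    "log_transform",
    "quantile_normalize",
    "ExpressedGeneFilter",
    "Log2FpkmTransform",
    "QuantileNormalizer",
]


# ---------------------------------------------------------------------------
# kernels (genes on axis 0, samples on axis 1)

def _check_fpkm(values: np.ndarray) -> None:
    if values.size == 0:
        raise ValueError("empty expression matrix")
    if np.isnan(values).any():
        raise ValueError("missing values are not supported (and are not imputed)")
    if (values < 0).any():
        raise ValueError("FPKM values must be nonnegative")


def _qn_assign(column: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Assign sorted reference values to one column by rank, averaging ties."""
    order = np.argsort(column, kind="mergesort")
    assigned = np.empty_like(reference)
    assigned[order] = reference
    # ties: each run of equal input values receives the mean reference value
    sorted_vals = column[order]
    boundaries = np.flatnonzero(sorted_vals[1:] != sorted_vals[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [column.size]])
    for a, b in zip(starts, ends):
        if b - a > 1:
            assigned[order[a:b]] = reference[a:b].mean()
    return assigned


def _qn_kernel(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        out[:, j] = _qn_assign(values[:, j], reference)
    return out


# ---------------------------------------------------------------------------
# DataFrame surface (genes x samples)

def filter_expressed(fpkm: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Retain genes whose FPKM exceeds ``threshold`` (strictly) in >= 1 sample.

    Row order and the sample set are preserved; the operation is idempotent.
    Raises :class:`EmptyResultError` when no gene passes, which usually means
    the threshold should be reviewed for the data at hand.
    """
    values = fpkm.to_numpy(dtype=float)
    _check_fpkm(values)
    keep = values.max(axis=1) > threshold
    if not keep.any():
        raise EmptyResultError(
            f"no gene has FPKM > {threshold} in any sample; review the expression threshold"
        )
    return fpkm.loc[keep]


def log_transform(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Transform FPKM to the log2(FPKM + 1) scale (0 maps to 0, 1 to 1, 3 to 2)."""
    values = fpkm.to_numpy(dtype=float)
    _check_fpkm(values)
    return pd.DataFrame(np.log2(values + 1.0), index=fpkm.index, columns=fpkm.columns)


def quantile_normalize(logm: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples by the classic sort--average--reassign rule.

    The k-th smallest value of every sample is replaced by the mean over
    samples of the k-th smallest values; ties within a sample receive the
    mean of the reference values at the tied ranks. After normalization every
    sample holds exactly the same multiset of values, within-sample rank
    order is preserved, and a second application is the identity.
    """
    if logm.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    values = logm.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values are not supported")
    reference = np.sort(values, axis=0).mean(axis=1)
    return pd.DataFrame(_qn_kernel(values, reference), index=logm.index, columns=logm.columns)


# ---------------------------------------------------------------------------
# scikit-learn transformers (samples x genes)

def _as_2d_array(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D array of shape (n_samples, n_genes)")
    return arr


class ExpressedGeneFilter(TransformerMixin, BaseEstimator):
    """Feature selector keeping genes with max FPKM strictly above a threshold.

    Parameters
    ----------
    threshold : float, default 1.0
        A gene is retained when its FPKM exceeds this value in at least one
        sample (strict inequality).

    Attributes
    ----------
    support_ : bool ndarray of shape (n_genes,)
        Mask of retained genes.
    n_features_in_ : int
    """

    def __init__(self, threshold: float = 1.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        arr = _as_2d_array(X)
        _check_fpkm(arr)
        self.n_features_in_ = arr.shape[1]
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.support_ = arr.max(axis=0) > self.threshold
        if not self.support_.any():
            raise EmptyResultError(
                f"no gene has FPKM > {self.threshold} in any sample; "
                "review the expression threshold"
            )
        return self

    def transform(self, X):
        if hasattr(X, "iloc"):
            return X.iloc[:, self.support_]
        return _as_2d_array(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        return self.support_


class Log2FpkmTransform(TransformerMixin, BaseEstimator):
    """Stateless transform of FPKM to log2(FPKM + 1) and back."""

    def fit(self, X, y=None):
        arr = _as_2d_array(X)
        _check_fpkm(arr)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        arr = _as_2d_array(X)
        _check_fpkm(arr)
        out = np.log2(arr + 1.0)
        if hasattr(X, "iloc"):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out

    def inverse_transform(self, X):
        arr = _as_2d_array(X)
        return np.exp2(arr) - 1.0


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Quantile normalization with a reference distribution learned at fit time.

    ``fit`` stores the mean sorted profile over the fitted samples;
    ``transform`` reassigns each sample's values to that reference by rank,
    averaging over ties. ``fit_transform`` on a matrix therefore reproduces
    the classic joint sort--average--reassign procedure.

    Attributes
    ----------
    reference_distribution_ : ndarray of shape (n_genes,)
        Sorted reference values shared by all normalized samples.
    """

    def fit(self, X, y=None):
        arr = _as_2d_array(X)
        if arr.shape[0] < 2:
            raise ValueError("quantile normalization requires at least 2 samples")
        if np.isnan(arr).any():
            raise ValueError("missing values are not supported")
        self.n_features_in_ = arr.shape[1]
        self.reference_distribution_ = np.sort(arr, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        arr = _as_2d_array(X)
        if arr.shape[1] != self.reference_distribution_.size:
            raise ValueError("number of genes differs from the fitted reference")
        out = _qn_kernel(arr.T, self.reference_distribution_).T
        if hasattr(X, "iloc"):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out
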