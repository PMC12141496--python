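"""Normalization, filtering, row standardization, and exploratory PCA.

Counts are brought onto a comparable scale with median-of-ratios size
factors and a log2(normalized + pseudocount) transform; exploration
uses PCA on the most variable genes, the conventional first look at a
bulk RNA-seq design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "size_factors_median_of_ratios",
    "normalize_log",
    "filter_low_expression",
    "zscore_rows",
    "pca_top_variable",
    "PCAResult",
]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over reference genes
    (genes positive in every sample) of that sample's count divided by
    the gene's geometric mean across samples.

    Raises
    ------
    ValueError
        If no gene is positive in all samples; use a pseudo-reference
        (e.g. add a pseudocount before estimation) in that case.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; size factors are "
            "undefined — consider a pseudocount-based pseudo-reference"
        )
    ref = x[positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    s = np.median(ref / geomean[:, None], axis=0)
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize_log(
    counts: pd.DataFrame, size_factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), elementwise."""
    s = size_factors.reindex(counts.columns)
    if s.isna().any() or (s <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    return np.log2(counts.div(s, axis=1) + pseudocount)


def filter_low_expression(counts: pd.DataFrame, min_mean: float = 10.0) -> pd.DataFrame:
    """Keep genes whose mean raw count is >= ``min_mean`` (order kept)."""
    keep = counts.mean(axis=1) >= min_mean
    if not keep.any():
        warnings.warn("no gene passes the expression filter", stacklevel=2)
    return counts.loc[keep]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1 (sample sd, denominator n-1).

    Constant rows cannot be standardized and are mapped to zeros with a
    warning, matching heatmap practice.
    """
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) mapped to zeros", stacklevel=2
        )
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class PCAResult:
    """Sample-space PCA of the most variable genes."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_ratio: np.ndarray  # fraction of variance per component
    genes_used: list[str]
    mean_: np.ndarray  # per-gene centering offsets

    def reconstruct(self) -> pd.DataFrame:
        """Genes x samples reconstruction from all retained components."""
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T + self.mean_
        return pd.DataFrame(
            x.T, index=pd.Index(self.genes_used, name="gene"), columns=self.scores.index
        )


def pca_top_variable(matrix: pd.DataFrame, n_top: int = 500) -> PCAResult:
    """PCA of samples over the ``n_top`` most variable genes.

    Rows (genes) are ranked by variance, ties broken lexicographically
    by gene id; rows are centered but not scaled before the
    decomposition.  All ``min(n_samples, n_genes_used)`` components are
    retained so the centered matrix can be reconstructed exactly.
    """
    if n_top < 2:
        raise ValueError("n_top must be >= 2")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    variances = matrix.var(axis=1, ddof=1)
    if float(variances.max()) == 0.0:
        raise ValueError("matrix has no variance; PCA is undefined")
    if n_top > len(matrix):
        warnings.warn(
            f"n_top={n_top} exceeds the {len(matrix)} available genes; using all",
            stacklevel=2,
        )
        n_top = len(matrix)
    order = pd.DataFrame(
        {"var": -variances.to_numpy(), "id": variances.index.to_numpy()}
    ).sort_values(["var", "id"], kind="mergesort")
    genes = order["id"].head(n_top).tolist()
    sub = matrix.loc[genes]

    X = sub.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=sub.index, columns=comp_names),
        variance_ratio=pca.explained_variance_ratio_,
        genes_used=genes,
        mean_=pca.mean_,
    )
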