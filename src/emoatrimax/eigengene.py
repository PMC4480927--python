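"""Eigengene extraction per tricluster and key-gene ranking.

The *eigengene* of a tricluster is a one-dimensional summary expression
profile: the dominant right singular vector of the tricluster's
standardized gene x (sample * time) matrix.  Member genes are then ranked
by their Pearson correlation with the eigengene; the top-ranked genes
("key genes", conventionally the top 10) are the tricluster's most
representative members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ExpressionTensor, Tricluster
from .exceptions import TriclusterError

__all__ = ["EigengeneResult", "KeyGeneRanking", "tricluster_eigengene", "key_genes"]


@dataclass(frozen=True)
class EigengeneResult:
    """Dominant singular triple of a tricluster's standardized expression.

    ``eigengene`` has unit Euclidean norm and length ``|J| * |K|``
    (sample-major flattening: all time points of the first member sample,
    then the second, ...).  Its sign is fixed so the sum of member-gene
    correlations is nonnegative.  ``explained_fraction`` is the first
    squared singular value over the total.
    """

    eigengene: np.ndarray
    singular_values: tuple
    explained_fraction: float
    gene_correlations: tuple


@dataclass(frozen=True)
class KeyGeneRanking:
    """Gene labels with Pearson correlation to the eigengene, descending."""

    genes: tuple  # of (label, correlation)


def _flat_profiles(tensor: ExpressionTensor, tric: Tricluster) -> np.ndarray:
    """Gene x (sample*time) matrix, sample-major, missing cells row-mean imputed."""
    sub = tensor.nan_values[np.ix_(tric.gene_idx, tric.sample_idx, tric.time_idx)]
    X = sub.reshape(len(tric.gene_idx), -1)
    if np.isnan(X).any():
        row_mean = np.nanmean(X, axis=1, keepdims=True)
        if np.isnan(row_mean).any():
            raise TriclusterError("a member gene has no observed cell")
        X = np.where(np.isnan(X), row_mean, X)
    return X


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            "constant gene profile(s) standardized to zero rows",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(flat[:, None], 0.0, (X - mu) / np.where(sd == 0, 1.0, sd))
    return Z


def _pearson_rows(X: np.ndarray, e: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(ec)
    num = Xc @ ec
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), 0.0)
    return np.clip(r, -1.0, 1.0)


def tricluster_eigengene(tensor: ExpressionTensor, tric: Tricluster) -> EigengeneResult:
    """SVD-based eigengene of a tricluster.

    Gene profiles are standardized to mean 0 / variance 1, the thin SVD
    ``X = U D V^T`` is taken, and the right singular vector belonging to
    the largest singular value is returned (the direction along which the
    standardized expression varies most, i.e. the shared profile).
    """
    if len(tric.gene_idx) < 2:
        raise TriclusterError("eigengene extraction requires at least two genes")
    Z = _standardize_rows(_flat_profiles(tensor, tric))
    if not Z.any():
        raise TriclusterError("all member profiles are constant; eigengene undefined")
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    corr = _pearson_rows(Z, e)
    if corr.sum() < 0:
        e = -e
        corr = -corr
    total = float((s * s).sum())
    return EigengeneResult(
        eigengene=e,
        singular_values=tuple(float(x) for x in s),
        explained_fraction=float(s[0] * s[0] / total),
        gene_correlations=tuple(float(c) for c in corr),
    )


def key_genes(tensor: ExpressionTensor, tric: Tricluster, top_k: int = 10) -> KeyGeneRanking:
    """Member genes ranked by Pearson correlation with the eigengene.

    Returns the ``top_k`` labels (default 10) in non-increasing
    correlation order, ties broken by gene label; if ``top_k`` exceeds the
    member count all genes are returned with a warning.
    """
    if top_k < 1:
        raise TriclusterError("top_k must be >= 1")
    result = tricluster_eigengene(tensor, tric)
    labels = [tensor.gene_ids[i] for i in tric.gene_idx]
    ranked = sorted(zip(labels, result.gene_correlations), key=lambda x: (-x[1], x[0]))
    if top_k > len(ranked):
        warnings.warn(
            f"top_k={top_k} exceeds the member count {len(ranked)}; returning all",
            RuntimeWarning,
            stacklevel=2,
        )
        top_k = len(ranked)
    return KeyGeneRanking(genes=tuple(ranked[:top_k]))
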