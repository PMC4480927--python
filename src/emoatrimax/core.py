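"""3D expression tensors, triclusters and the shifting-model coherence score.

A time-series expression experiment measures ``G`` genes over ``C``
biological replicates (samples) at ``T`` time points.  The measurements
form a real tensor ``D`` of shape ``G x C x T`` with entries ``d_ijk``.
A *tricluster* ``M(I, J, K)`` selects a subset of genes ``I``, samples
``J`` and time points ``K`` whose expression is expected to follow the
additive *shifting* model

    m_ijk = Gamma + alpha_i + beta_j + eta_k,

i.e. every member gene traces the same temporal shape up to per-gene,
per-sample and per-time offsets.  Coherence with that model is measured
by the mean squared residue (MSR),

    MSR = mean over cells of (m_ijk - m_iJK - m_IjK - m_IJk + 2 m_IJK)^2,

where ``m_iJK``, ``m_IjK``, ``m_IJk`` are the gene-, sample- and
time-slice means and ``m_IJK`` is the tricluster mean.  A perfect
shifting tricluster has MSR exactly zero; a *delta-tricluster* is one
with MSR at most a user ceiling ``delta``.

Missing values (a boolean observation mask) are supported: every mean is
taken over observed cells only, and residues are defined only for
observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    BoundsError,
    DegenerateSliceError,
    MissingCellError,
    TriclusterError,
)

__all__ = [
    "ExpressionTensor",
    "Tricluster",
    "TriclusterSet",
    "ShiftingParameters",
    "compute_msr",
    "residue",
    "residue_cube",
]


def _as_labels(labels: Iterable, axis: str) -> tuple:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        raise TriclusterError(f"duplicate {axis} labels")
    return labels


@dataclass(frozen=True)
class ExpressionTensor:
    """A ``G x C x T`` expression tensor with axis labels and an observation mask.

    Parameters
    ----------
    values
        Real array of shape ``(G, C, T)`` in arbitrary expression units.
    gene_ids, sample_ids, time_ids
        Unique labels per axis; time labels are kept in the given order.
    mask
        Boolean array of the same shape, ``True`` where the cell was
        observed.  Defaults to all-observed.
    """

    values: np.ndarray
    gene_ids: tuple
    sample_ids: tuple
    time_ids: tuple
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise TriclusterError("values must be a 3D array (genes x samples x times)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", _as_labels(self.gene_ids, "gene"))
        object.__setattr__(self, "sample_ids", _as_labels(self.sample_ids, "sample"))
        object.__setattr__(self, "time_ids", _as_labels(self.time_ids, "time"))
        G, C, T = values.shape
        if G < 2 or C < 1 or T < 2:
            raise TriclusterError("tensor requires G >= 2, C >= 1 and T >= 2")
        if (len(self.gene_ids), len(self.sample_ids), len(self.time_ids)) != (G, C, T):
            raise TriclusterError("axis label lists must match tensor dimensions")
        mask = self.mask
        if mask is None:
            mask = np.ones(values.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != values.shape:
                raise TriclusterError("mask shape must match values shape")
        object.__setattr__(self, "mask", mask)
        complete = bool(mask.all())
        object.__setattr__(self, "_complete", complete)
        nan_values = values if complete else np.where(mask, values, np.nan)
        object.__setattr__(self, "_nan_values", nan_values)

    # -- convenience ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    @property
    def complete(self) -> bool:
        """True when every cell is observed."""
        return self._complete  # type: ignore[attr-defined]

    @property
    def nan_values(self) -> np.ndarray:
        """Values with unobserved cells replaced by NaN."""
        return self._nan_values  # type: ignore[attr-defined]


def _normalize_axis(idx: Iterable[int], n: int, axis: str) -> tuple[int, ...]:
    arr = np.unique(np.asarray(list(idx), dtype=int))
    if arr.size == 0:
        raise TriclusterError(f"empty {axis} index set")
    if arr[0] < 0 or arr[-1] >= n:
        raise BoundsError(f"{axis} index out of range 0..{n - 1}")
    return tuple(int(i) for i in arr)


def _subtensor(tensor: ExpressionTensor, I, J, K) -> np.ndarray:
    """Sub-block of ``nan_values`` addressed by index tuples (may contain NaN)."""
    return tensor.nan_values[np.ix_(I, J, K)]


def _residues_from_block(sub: np.ndarray) -> np.ndarray:
    """Residue cube r_ijk for a sub-block with NaN marking unobserved cells.

    Raises :class:`DegenerateSliceError` when any gene/sample/time slice of
    the block has no observed cell, since the corresponding slice mean is
    then undefined.
    """
    if np.isnan(sub).any():
        obs = ~np.isnan(sub)
        if (
            (obs.sum(axis=(1, 2)) == 0).any()
            or (obs.sum(axis=(0, 2)) == 0).any()
            or (obs.sum(axis=(0, 1)) == 0).any()
        ):
            raise DegenerateSliceError("a tricluster slice contains no observed cell")
        gene_mean = np.nanmean(sub, axis=(1, 2), keepdims=True)
        sample_mean = np.nanmean(sub, axis=(0, 2), keepdims=True)
        time_mean = np.nanmean(sub, axis=(0, 1), keepdims=True)
        overall = np.nanmean(sub)
    else:
        gene_mean = sub.mean(axis=(1, 2), keepdims=True)
        sample_mean = sub.mean(axis=(0, 2), keepdims=True)
        time_mean = sub.mean(axis=(0, 1), keepdims=True)
        overall = sub.mean()
    return sub - gene_mean - sample_mean - time_mean + 2.0 * overall


def _msr_from_indices(tensor: ExpressionTensor, I, J, K) -> float:
    r = _residues_from_block(_subtensor(tensor, I, J, K))
    if np.isnan(r).any():
        return float(np.nanmean(r * r))
    return float(np.mean(r * r))


@dataclass(frozen=True)
class Tricluster:
    """Index subsets ``(I, J, K)`` into a tensor with cached MSR and volume.

    Build instances through :meth:`from_indices`, which sorts and
    de-duplicates the index sets, checks bounds and computes the cached
    fields against the referenced tensor.
    """

    gene_idx: tuple[int, ...]
    sample_idx: tuple[int, ...]
    time_idx: tuple[int, ...]
    msr: float
    volume: int

    @classmethod
    def from_indices(
        cls,
        tensor: ExpressionTensor,
        genes: Iterable[int],
        samples: Iterable[int],
        times: Iterable[int],
    ) -> "Tricluster":
        I = _normalize_axis(genes, tensor.n_genes, "gene")
        J = _normalize_axis(samples, tensor.n_samples, "sample")
        K = _normalize_axis(times, tensor.n_times, "time")
        msr = _msr_from_indices(tensor, I, J, K)
        return cls(I, J, K, msr, len(I) * len(J) * len(K))

    @property
    def key(self) -> tuple:
        """Hashable identity of the membership (ignores cached fields)."""
        return (self.gene_idx, self.sample_idx, self.time_idx)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.gene_idx), len(self.sample_idx), len(self.time_idx))


def compute_msr(tensor: ExpressionTensor, tric: Tricluster) -> float:
    """Mean squared residue of ``tric`` on ``tensor`` (recomputed from scratch).

    Averages ``r_ijk**2`` over observed cells, where
    ``r_ijk = m_ijk - m_iJK - m_IjK - m_IJk + 2*m_IJK`` and all means are
    taken over observed cells.  Zero for a perfect shifting tricluster.
    """
    I = _normalize_axis(tric.gene_idx, tensor.n_genes, "gene")
    J = _normalize_axis(tric.sample_idx, tensor.n_samples, "sample")
    K = _normalize_axis(tric.time_idx, tensor.n_times, "time")
    return _msr_from_indices(tensor, I, J, K)


def residue_cube(tensor: ExpressionTensor, tric: Tricluster) -> np.ndarray:
    """Residues ``r_ijk`` for every cell of the tricluster (NaN where unobserved)."""
    return _residues_from_block(
        _subtensor(tensor, tric.gene_idx, tric.sample_idx, tric.time_idx)
    )


def residue(tensor: ExpressionTensor, tric: Tricluster, i: int, j: int, k: int) -> float:
    """Per-cell residue ``r_ijk`` for a member cell ``(i, j, k)`` (tensor indices)."""
    try:
        a = tric.gene_idx.index(i)
        b = tric.sample_idx.index(j)
        c = tric.time_idx.index(k)
    except ValueError as exc:
        raise BoundsError(f"cell ({i}, {j}, {k}) is not a member of the tricluster") from exc
    if not tensor.mask[i, j, k]:
        raise MissingCellError(f"cell ({i}, {j}, {k}) is unobserved")
    return float(residue_cube(tensor, tric)[a, b, c])


@dataclass(frozen=True)
class ShiftingParameters:
    """Parameters ``Gamma, alpha_i, beta_j, eta_k`` of a perfect shifting tricluster."""

    gamma: float
    alpha: np.ndarray
    beta: np.ndarray
    eta: np.ndarray

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "eta"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def block(self) -> np.ndarray:
        """Reconstruct the block: ``m_ijk = gamma + alpha_i + beta_j + eta_k``."""
        return (
            self.gamma
            + self.alpha[:, None, None]
            + self.beta[None, :, None]
            + self.eta[None, None, :]
        )


@dataclass(frozen=True)
class TriclusterSet:
    """An ordered collection of triclusters over a common label space.

    Carries provenance (configuration, seed, convergence trace) so a run
    is reproducible from its output alone.
    """

    triclusters: tuple[Tricluster, ...]
    gene_ids: tuple
    sample_ids: tuple
    time_ids: tuple
    objectives: tuple | None = None
    provenance: Mapping = field(default_factory=dict)
    traces: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "triclusters", tuple(self.triclusters))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "time_ids", tuple(self.time_ids))

    def __len__(self) -> int:
        return len(self.triclusters)

    def __iter__(self):
        return iter(self.triclusters)

    def __getitem__(self, i: int) -> Tricluster:
        return self.triclusters[i]

    def label_sets(self, i: int) -> tuple[frozenset, frozenset, frozenset]:
        """Gene/sample/time label sets of the ``i``-th tricluster."""
        t = self.triclusters[i]
        return (
            frozenset(self.gene_ids[g] for g in t.gene_idx),
            frozenset(self.sample_ids[s] for s in t.sample_idx),
            frozenset(self.time_ids[k] for k in t.time_idx),
        )
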