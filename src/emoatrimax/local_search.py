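"""Greedy repair of candidate triclusters into delta-triclusters.

The evolutionary engine proposes arbitrary index subsets; this module
repairs them with the three-phase greedy heuristic of the delta-TRIMAX
family (a Cheng-Church-style generalization to three axes):

1. *multiple node deletion* — while the MSR exceeds ``delta``, drop every
   gene / sample / time point whose mean squared residue exceeds
   ``lambda * MSR`` (one axis at a time, recomputing MSR between phases);
2. *single node deletion* — remove the single worst node per iteration
   until the MSR falls to ``delta`` or the size floors are reached;
3. *node addition* — re-grow the tricluster to a maximal delta-tricluster
   by admitting every outside node whose mean squared residue does not
   exceed the current MSR.

Tie-breaking is deterministic everywhere: axis order gene -> sample ->
time, then ascending index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionTensor, Tricluster, _residues_from_block, _subtensor
from .exceptions import DegenerateSliceError, TriclusterError

__all__ = [
    "LocalSearchConfig",
    "RepairResult",
    "multiple_node_deletion",
    "single_node_deletion",
    "node_addition",
    "repair",
]

# Numeric slack when comparing candidate node residues against an MSR that
# is zero up to floating-point cancellation noise; without it a perfect
# shifting block could never be re-grown to its maximal extent.
_ADD_TOL = 1e-12


@dataclass(frozen=True)
class LocalSearchConfig:
    """Knobs of the greedy repair.

    Parameters
    ----------
    delta
        MSR ceiling defining a delta-tricluster (``delta >= 0``).
    lambda_
        Deletion aggressiveness multiplier (> 1); multiple node deletion
        drops nodes whose mean squared residue exceeds ``lambda_ * MSR``.
    min_genes, min_samples, min_times
        Size floors below which an axis is never shrunk.
    multiple_deletion_min_axis
        Multiple deletion is skipped on axes shorter than this (single
        deletion handles small axes without overshooting).
    """

    delta: float
    lambda_: float = 1.2
    min_genes: int = 2
    min_samples: int = 1
    min_times: int = 2
    multiple_deletion_min_axis: int = 50

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise TriclusterError("delta must be nonnegative")
        if self.lambda_ <= 1:
            raise TriclusterError("lambda_ must exceed 1")
        if min(self.min_genes, self.min_samples, self.min_times) < 1:
            raise TriclusterError("size floors must be >= 1")

    @property
    def floors(self) -> tuple[int, int, int]:
        return (self.min_genes, self.min_samples, self.min_times)


@dataclass(frozen=True)
class RepairResult:
    """Outcome of :func:`repair`; ``feasible`` is False when the tricluster
    reached its size floors with MSR still above ``delta``."""

    tricluster: Tricluster
    feasible: bool


def _scores(tensor: ExpressionTensor, I, J, K):
    """MSR plus per-node mean squared residues along each axis."""
    sub = _subtensor(tensor, I, J, K)
    r = _residues_from_block(sub)
    r2 = r * r
    if np.isnan(r2).any():
        msr = float(np.nanmean(r2))
        g = np.nanmean(r2, axis=(1, 2))
        s = np.nanmean(r2, axis=(0, 2))
        t = np.nanmean(r2, axis=(0, 1))
    else:
        msr = float(r2.mean())
        g = r2.mean(axis=(1, 2))
        s = r2.mean(axis=(0, 2))
        t = r2.mean(axis=(0, 1))
    return msr, (g, s, t)


def _build(tensor: ExpressionTensor, axes) -> Tricluster:
    return Tricluster.from_indices(tensor, axes[0], axes[1], axes[2])


def _drop_fully_missing(tensor: ExpressionTensor, axes):
    """Remove nodes whose entire slice is unobserved (rare, AD-4-style data).

    Iterates because removing one axis' nodes can empty another axis'
    slices.  Raises if an axis would become empty.
    """
    if tensor.complete:
        return axes
    axes = [np.asarray(a, dtype=int) for a in axes]
    while True:
        obs = ~np.isnan(tensor.nan_values[np.ix_(*axes)])
        counts = [obs.sum(axis=(1, 2)), obs.sum(axis=(0, 2)), obs.sum(axis=(0, 1))]
        if all((c > 0).all() for c in counts):
            return [tuple(int(i) for i in a) for a in axes]
        for ax in range(3):
            keep = counts[ax] > 0
            if not keep.any():
                raise DegenerateSliceError("all slices of an axis are unobserved")
            axes[ax] = axes[ax][keep]


def multiple_node_deletion(
    tensor: ExpressionTensor, tric: Tricluster, cfg: LocalSearchConfig
) -> Tricluster:
    """Simultaneously delete every node scoring above ``lambda_ * MSR``.

    Phases run gene -> sample -> time with the MSR recomputed between
    phases; stops when the MSR reaches ``delta`` or no node exceeds the
    threshold.  Axes at their floor, or shorter than
    ``multiple_deletion_min_axis``, are left untouched.
    """
    axes = [np.asarray(a, dtype=int) for a in (tric.gene_idx, tric.sample_idx, tric.time_idx)]
    while True:
        changed = False
        done = False
        for ax in range(3):
            msr, per_node = _scores(tensor, *axes)
            if msr <= cfg.delta:
                done = True
                break
            arr = axes[ax]
            floor = cfg.floors[ax]
            if len(arr) <= floor or len(arr) < cfg.multiple_deletion_min_axis:
                continue
            sc = per_node[ax]
            flagged = np.where(sc > cfg.lambda_ * msr)[0]
            cap = len(arr) - floor
            if len(flagged) > cap:
                # keep the worst offenders; stable sort preserves the
                # ascending-index tie rule
                order = np.argsort(-sc[flagged], kind="stable")
                flagged = flagged[order][:cap]
            if len(flagged):
                axes[ax] = np.delete(arr, flagged)
                changed = True
        if done or not changed:
            break
    return _build(tensor, axes)


def single_node_deletion(
    tensor: ExpressionTensor, tric: Tricluster, cfg: LocalSearchConfig
) -> Tricluster:
    """Remove one worst node per iteration until ``MSR <= delta`` or floors."""
    axes = [np.asarray(a, dtype=int) for a in (tric.gene_idx, tric.sample_idx, tric.time_idx)]
    while True:
        msr, per_node = _scores(tensor, *axes)
        if msr <= cfg.delta:
            break
        best_ax, best_pos, best_score = -1, -1, -np.inf
        for ax in range(3):
            if len(axes[ax]) <= cfg.floors[ax]:
                continue
            pos = int(np.argmax(per_node[ax]))  # argmax takes the lowest index on ties
            score = float(per_node[ax][pos])
            if score > best_score:  # strict: earlier axis wins ties
                best_ax, best_pos, best_score = ax, pos, score
        if best_ax < 0:
            break  # every axis at its floor; caller flags infeasibility
        axes[best_ax] = np.delete(axes[best_ax], best_pos)
    return _build(tensor, axes)


def _candidate_scores(tensor, axes, ax, outside, means, overall):
    """Mean squared residue of each outside node w.r.t. the current tricluster."""
    I, J, K = axes
    gm, sm, tm = means
    if ax == 0:
        sub = tensor.nan_values[np.ix_(outside, J, K)]
        own = _nanmean_keep(sub, axis=(1, 2), keepdims=True)
        r = sub - own - sm[None, :, None] - tm[None, None, :] + 2.0 * overall
        return _nanmean_axis(r * r, axis=(1, 2))
    if ax == 1:
        sub = tensor.nan_values[np.ix_(I, outside, K)]
        own = _nanmean_keep(sub, axis=(0, 2), keepdims=True)
        r = sub - gm[:, None, None] - own - tm[None, None, :] + 2.0 * overall
        return _nanmean_axis(r * r, axis=(0, 2))
    sub = tensor.nan_values[np.ix_(I, J, outside)]
    own = _nanmean_keep(sub, axis=(0, 1), keepdims=True)
    r = sub - gm[:, None, None] - sm[None, :, None] - own + 2.0 * overall
    return _nanmean_axis(r * r, axis=(0, 1))


def _nanmean_keep(a, axis, keepdims):
    if np.isnan(a).any():
        cnt = (~np.isnan(a)).sum(axis=axis, keepdims=keepdims)
        s = np.nansum(a, axis=axis, keepdims=keepdims)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return a.mean(axis=axis, keepdims=keepdims)


def _nanmean_axis(a, axis):
    """Mean over ``axis`` ignoring NaN; empty rows score +inf (never admitted)."""
    if np.isnan(a).any():
        cnt = (~np.isnan(a)).sum(axis=axis)
        s = np.nansum(a, axis=axis)
        out = np.full(cnt.shape, np.inf)
        np.divide(s, cnt, out=out, where=cnt > 0)
        return out
    return a.mean(axis=axis)


def node_addition(
    tensor: ExpressionTensor, tric: Tricluster, cfg: LocalSearchConfig
) -> Tricluster:
    """Grow a delta-tricluster to a maximal one.

    Repeated passes over genes, samples and time points add every outside
    node whose mean squared residue against the current tricluster is at
    most the current MSR; a pass that would push the MSR above ``delta``
    is reverted for that axis.  Terminates when a full pass adds nothing;
    the delta property is preserved.
    """
    if tric.msr > cfg.delta + _ADD_TOL:
        raise TriclusterError("node_addition requires MSR <= delta")
    axes = [np.asarray(a, dtype=int) for a in (tric.gene_idx, tric.sample_idx, tric.time_idx)]
    limits = tensor.shape
    while True:
        changed = False
        for ax in range(3):
            sub = _subtensor(tensor, *axes)
            r = _residues_from_block(sub)
            r2 = r * r
            msr = float(np.nanmean(r2)) if np.isnan(r2).any() else float(r2.mean())
            gm = _nanmean_keep(sub, axis=(1, 2), keepdims=False)
            sm = _nanmean_keep(sub, axis=(0, 2), keepdims=False)
            tm = _nanmean_keep(sub, axis=(0, 1), keepdims=False)
            overall = float(np.nanmean(sub)) if np.isnan(sub).any() else float(sub.mean())
            outside = np.setdiff1d(np.arange(limits[ax]), axes[ax])
            if outside.size == 0:
                continue
            sc = _candidate_scores(tensor, axes, ax, outside, (gm, sm, tm), overall)
            take = outside[sc <= msr + _ADD_TOL]
            if take.size == 0:
                continue
            candidate = [a.copy() for a in axes]
            candidate[ax] = np.sort(np.concatenate([axes[ax], take]))
            new_msr, _ = _scores(tensor, *candidate)
            if new_msr > cfg.delta + _ADD_TOL:
                continue  # revert: growth would break the delta property
            axes = candidate
            changed = True
        if not changed:
            break
    return _build(tensor, axes)


def repair(tensor: ExpressionTensor, tric: Tricluster, cfg: LocalSearchConfig) -> RepairResult:
    """Full repair: multiple deletion -> single deletion -> addition.

    Returns a :class:`RepairResult`; ``feasible`` is False when the
    candidate reached the size floors with MSR still above ``delta`` (the
    caller typically re-seeds such individuals).
    """
    if not tensor.complete:
        axes = _drop_fully_missing(
            tensor, (tric.gene_idx, tric.sample_idx, tric.time_idx)
        )
        tric = _build(tensor, axes)
    t = multiple_node_deletion(tensor, tric, cfg)
    t = single_node_deletion(tensor, t, cfg)
    if t.msr <= cfg.delta:
        t = node_addition(tensor, t, cfg)
        return RepairResult(t, True)
    return RepairResult(t, False)
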