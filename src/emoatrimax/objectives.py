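"""The three objective functions evaluated on every delta-tricluster.

* ``f1 = MSR / delta`` — normalized coherence, minimized;
* ``f2 = |I||J||K| / (G C T)`` — volume fraction, maximized;
* ``f3`` — mean absolute Spearman rank correlation between the member
  genes' time profiles (expression averaged over member samples),
  maximized.  Absolute values are taken because co-regulated genes can be
  either up- or down-regulated, so perfectly anti-correlated profiles are
  as informative as perfectly correlated ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import ExpressionTensor, Tricluster, _subtensor
from .exceptions import DegenerateProfileError, TriclusterError

__all__ = [
    "ObjectiveVector",
    "objective_f1",
    "objective_f2",
    "objective_f3",
    "evaluate_objectives",
    "MSR_ZERO_TOL",
]

# An MSR below this is indistinguishable from exact shifting coherence at
# double precision (residues of a perfect block cancel only up to
# floating-point rounding); f1 treats such values as exactly zero so that
# equally perfect triclusters compare as equals.
MSR_ZERO_TOL = 1e-9


@dataclass(frozen=True)
class ObjectiveVector:
    """The triple ``(f1, f2, f3)`` for one candidate tricluster."""

    f1: float
    f2: float
    f3: float

    def min_frame(self) -> np.ndarray:
        """Common minimization frame: f2 and f3 are negated."""
        return np.array([self.f1, -self.f2, -self.f3])

    def sum_deficit(self) -> float:
        """``f1 + (1 - f2) + (1 - f3)`` — the per-solution convergence summand."""
        return self.f1 + (1.0 - self.f2) + (1.0 - self.f3)


def objective_f1(tensor: ExpressionTensor, tric: Tricluster, delta: float) -> float:
    """Normalized MSR, ``MSR / delta``; at most 1 for a delta-tricluster."""
    if delta <= 0:
        raise TriclusterError("delta must be positive for f1")
    if tric.msr <= MSR_ZERO_TOL:
        return 0.0
    return tric.msr / delta

def objective_f2(tensor: ExpressionTensor, tric: Tricluster) -> float:
    """Tricluster volume as a fraction of the tensor volume."""
    G, C, T = tensor.shape
    return tric.volume / (G * C * T)


def objective_f3(tensor: ExpressionTensor, tric: Tricluster) -> float:
    """Mean absolute Spearman correlation over all member gene pairs.

    For each gene the expression is averaged over the member samples at
    each member time point; the resulting time profiles are ranked
    (fractional ranks on ties) and, for every unordered pair of genes,
    ``rho = 1 - 6 * sum(d_i^2) / (n (n^2 - 1))`` with ``d_i`` the rank
    difference at time point ``i`` and ``n`` the number of member time
    points.  Returns the mean of ``|rho|``.

    Requires at least three member time points.  A gene whose profile is
    constant has no defined ranking direction; its pairs contribute 0
    (with a warning).  With fewer than two genes the score is vacuously 1.
    """
    n = len(tric.time_idx)
    if n < 3:
        raise DegenerateProfileError("f3 requires at least 3 member time points")
    g = len(tric.gene_idx)
    if g < 2:
        return 1.0
    sub = _subtensor(tensor, tric.gene_idx, tric.sample_idx, tric.time_idx)
    if np.isnan(sub).any():
        profile = _nan_profile(sub)
    else:
        profile = sub.mean(axis=1)
    ranks = rankdata(profile, axis=1, method="average")
    spread = profile.max(axis=1) - profile.min(axis=1)
    constant = spread == 0
    d2 = (
        (ranks * ranks).sum(axis=1)[:, None]
        + (ranks * ranks).sum(axis=1)[None, :]
        - 2.0 * ranks @ ranks.T
    )
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    score = np.clip(np.abs(rho), 0.0, 1.0)
    if constant.any():
        warnings.warn(
            "constant time profile(s); affected gene pairs contribute |rho| = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        score[constant, :] = 0.0
        score[:, constant] = 0.0
    iu = np.triu_indices(g, k=1)
    return float(score[iu].mean())


def _nan_profile(sub: np.ndarray) -> np.ndarray:
    """Sample-averaged profiles; (gene, time) cells with no observed sample
    are imputed with the gene's own profile mean (mid rank)."""
    cnt = (~np.isnan(sub)).sum(axis=1)
    s = np.nansum(sub, axis=1)
    with np.errstate(invalid="ignore"):
        profile = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    if np.isnan(profile).any():
        warnings.warn(
            "time-profile cells with no observed sample were mean-imputed",
            RuntimeWarning,
            stacklevel=3,
        )
        row_mean = np.nanmean(profile, axis=1, keepdims=True)
        profile = np.where(np.isnan(profile), row_mean, profile)
    return profile


def evaluate_objectives(
    tensor: ExpressionTensor, tric: Tricluster, delta: float
) -> ObjectiveVector:
    """All three objectives for one tricluster."""
    return ObjectiveVector(
        objective_f1(tensor, tric, delta),
        objective_f2(tensor, tric),
        objective_f3(tensor, tric),
    )
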