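"""Evaluation statistics for tricluster sets.

Covers: the affirmation (recovery) score against an implanted ground
truth, tricluster diffusion (TD), statistical difference from background
(SDB), hypergeometric gene-set enrichment with hit scores and a
random-gene-list significance test, the randomized ``delta`` estimation
heuristic, and the replicate-distance summary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .core import ExpressionTensor, Tricluster, TriclusterSet, _msr_from_indices
from .exceptions import TriclusterError
from .objectives import MSR_ZERO_TOL as _MSR_ZERO

__all__ = [
    "MatchReport",
    "AnnotationCollection",
    "EnrichedTerm",
    "affirmation_score",
    "tricluster_diffusion",
    "sdb_score",
    "enrich_gene_sets",
    "hit_score",
    "hit_score_significance",
    "estimate_delta",
    "replicate_distance_summary",
]


# ---------------------------------------------------------------------------
# Affirmation score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchReport:
    """Recovery report between an implanted and a recovered tricluster set.

    ``overall`` is the geometric mean of the per-axis components, so
    ``overall ** 2 == gene * sample * time`` component product up to
    rounding; it equals 1 exactly when every recovered tricluster matches
    an implanted one on all three axes.
    """

    overall: float
    gene_component: float
    sample_component: float
    time_component: float
    best_matches: tuple = ()


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def affirmation_score(implanted: TriclusterSet, recovered: TriclusterSet) -> MatchReport:
    """Affirmation score ``SM*`` between implanted and recovered sets.

    Each axis component is the average, over the recovered triclusters, of
    the best Jaccard overlap of that axis' member set against any
    implanted tricluster (the score of the result set with respect to the
    implanted set).  The overall score is the geometric mean of the three
    axis components; it ranges over [0, 1] and equals 1 when the recovered
    set coincides with the implanted set.
    """
    if len(implanted) == 0 or len(recovered) == 0:
        raise TriclusterError("affirmation_score requires non-empty tricluster sets")
    im = [implanted.label_sets(i) for i in range(len(implanted))]
    res = [recovered.label_sets(i) for i in range(len(recovered))]
    components = np.zeros(3)
    matches = []
    for sets_r in res:
        best = np.zeros(3)
        best_id = [-1, -1, -1]
        for m, sets_i in enumerate(im):
            for ax in range(3):
                j = _jaccard(sets_r[ax], sets_i[ax])
                if j > best[ax]:
                    best[ax] = j
                    best_id[ax] = m
        components += best
        matches.append(
            {
                "gene_match": best_id[0],
                "sample_match": best_id[1],
                "time_match": best_id[2],
                "gene_jaccard": float(best[0]),
                "sample_jaccard": float(best[1]),
                "time_jaccard": float(best[2]),
            }
        )
    components /= len(res)
    overall = float(np.sqrt(components[0] * components[1] * components[2]))
    return MatchReport(
        overall=overall,
        gene_component=float(components[0]),
        sample_component=float(components[1]),
        time_component=float(components[2]),
        best_matches=tuple(matches),
    )


# ---------------------------------------------------------------------------
# TD and SDB
# ---------------------------------------------------------------------------

def tricluster_diffusion(tric: Tricluster) -> float:
    """``TD = MSR / volume``; lower means a tighter, larger tricluster."""
    if tric.volume <= 0:
        raise TriclusterError("volume must be positive")
    return tric.msr / tric.volume


def sdb_score(
    tensor: ExpressionTensor,
    trics: TriclusterSet | Sequence[Tricluster],
    r: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """Statistical difference from the background data matrix.

    For each tricluster ``i``, draws ``r`` random triclusters of the same
    gene/sample/time counts (uniform axis subsets without replacement) and
    evaluates ``(mean_j RMSR_j - MSR_i) / MSR_i``; the SDB score is the
    average over triclusters.  Higher is better.  Triclusters with MSR = 0
    are skipped with a warning (the ratio is undefined).
    """
    if r < 1:
        raise TriclusterError("r must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    G, C, T = tensor.shape
    terms = []
    for tric in trics:
        if tric.msr <= _MSR_ZERO:
            # the relative excess is undefined at MSR 0 (and explodes for
            # MSR at floating-point cancellation level)
            warnings.warn(
                "skipping a tricluster with MSR = 0 in the SDB score",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        g, c, t = tric.shape
        rmsr = np.empty(r)
        for j in range(r):
            I = np.sort(rng.choice(G, size=g, replace=False))
            J = np.sort(rng.choice(C, size=c, replace=False))
            K = np.sort(rng.choice(T, size=t, replace=False))
            rmsr[j] = _msr_from_indices(tensor, I, J, K)
        terms.append((rmsr.mean() - tric.msr) / tric.msr)
    if not terms:
        warnings.warn("no tricluster with positive MSR; SDB undefined", RuntimeWarning)
        return float("nan")
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# Gene-set enrichment and hit scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationCollection:
    """Named gene sets (e.g. pathways or TF target sets) over a gene universe."""

    sets: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        sets = {str(k): frozenset(map(str, v)) for k, v in self.sets.items()}
        universe = frozenset(map(str, self.universe))
        if not universe:
            raise TriclusterError("annotation universe must be non-empty")
        for name, genes in sets.items():
            if not genes <= universe:
                raise TriclusterError(f"annotation set {name!r} is not within the universe")
        object.__setattr__(self, "sets", sets)
        object.__setattr__(self, "universe", universe)


@dataclass(frozen=True)
class EnrichedTerm:
    name: str
    overlap: frozenset
    p_value: float
    adjusted_p: float


def enrich_gene_sets(
    tric_genes: Iterable,
    annotations: AnnotationCollection,
    alpha: float = 0.05,
    method: str = "bh",
) -> list[EnrichedTerm]:
    """Hypergeometric over-representation test per annotation set.

    ``method`` selects the multiple-testing correction: ``"bh"``
    (Benjamini-Hochberg, suited to pathway-style annotations) or ``"by"``
    (Benjamini-Yekutieli, suited to correlated TF-binding-site sets).
    Returns the sets with corrected p <= alpha and at least one
    overlapping gene, sorted by raw p-value.
    """
    genes = frozenset(map(str, tric_genes))
    if not genes <= annotations.universe:
        raise TriclusterError("tricluster genes must be a subset of the universe")
    if method not in ("bh", "by"):
        raise TriclusterError("correction method must be 'bh' or 'by'")
    M = len(annotations.universe)
    N = len(genes)
    names = sorted(annotations.sets)
    pvals = []
    overlaps = []
    for name in names:
        term = annotations.sets[name]
        k = len(genes & term)
        overlaps.append(genes & term)
        # P(X >= k) for X ~ Hypergeometric(M, |term|, N)
        pvals.append(float(stats.hypergeom.sf(k - 1, M, len(term), N)))
    if not names:
        return []
    _, adjusted, _, _ = multipletests(pvals, method=f"fdr_{method}")
    out = [
        EnrichedTerm(name, overlap, p, float(ap))
        for name, overlap, p, ap in zip(names, overlaps, pvals, adjusted)
        if ap <= alpha and len(overlap) >= 1
    ]
    out.sort(key=lambda t: (t.p_value, t.name))
    return out


def hit_score(tric_genes: Iterable, enriched: Sequence[EnrichedTerm]) -> float:
    """Largest enriched-term overlap divided by the tricluster's gene count.

    A higher hit score means more of the tricluster's genes participate in
    a single annotated category; 0.0 when nothing is enriched.
    """
    genes = frozenset(map(str, tric_genes))
    if not genes:
        raise TriclusterError("tricluster gene set must be non-empty")
    if not enriched:
        return 0.0
    return max(len(t.overlap) for t in enriched) / len(genes)


def _ratio_vector(genes, annotations, alpha, method) -> list[float]:
    terms = enrich_gene_sets(genes, annotations, alpha=alpha, method=method)
    if not terms:
        return [0.0]
    return [len(t.overlap) / len(frozenset(genes)) for t in terms]


def hit_score_significance(
    tric_genes: Iterable,
    annotations: AnnotationCollection,
    n_random: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    method: str = "bh",
) -> float:
    """Rank-sum significance of a tricluster's enrichment signal.

    Draws ``n_random`` uniform gene lists of the tricluster's size from
    the universe, computes per-enriched-term overlap ratios for the
    tricluster and for each random list (a list with no enrichment
    contributes a single 0), and returns the two-sided
    Mann-Whitney-Wilcoxon p-value comparing the two score collections.
    """
    if n_random < 2:
        raise TriclusterError("n_random must be >= 2")
    genes = sorted(frozenset(map(str, tric_genes)))
    universe = sorted(annotations.universe)
    if len(universe) < len(genes):
        raise TriclusterError("universe smaller than the tricluster gene list")
    rng = rng if rng is not None else np.random.default_rng()
    observed = _ratio_vector(genes, annotations, alpha, method)
    background: list[float] = []
    for _ in range(n_random):
        draw = rng.choice(len(universe), size=len(genes), replace=False)
        background.extend(
            _ratio_vector([universe[i] for i in draw], annotations, alpha, method)
        )
    pooled = observed + background
    if max(pooled) == min(pooled):
        return 1.0  # identical distributions; the rank-sum statistic is degenerate
    return float(stats.mannwhitneyu(observed, background, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# delta estimation
# ---------------------------------------------------------------------------

def estimate_delta(
    tensor: ExpressionTensor,
    k_genes: int | None = None,
    k_times: int = 2,
    repeats: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """Randomized MSR-floor heuristic for choosing ``delta``.

    Per repeat: genes are partitioned into ``k_genes`` groups by k-means
    on their sample-averaged time courses; within one randomly selected
    sample plane the time points of each gene group are partitioned into
    ``k_times`` groups; the MSR (single-sample tricluster form) of every
    gene-group x time-group submatrix with at least two genes and two time
    points is evaluated.  The lowest MSR observed across all repeats is
    returned.  Defaults: ``k_genes = ceil(sqrt(G))``, ``k_times = 2``,
    100 repeats.
    """
    if repeats < 1:
        raise TriclusterError("repeats must be >= 1")
    G, C, T = tensor.shape
    if k_genes is None:
        k_genes = math.ceil(math.sqrt(G))
    if k_genes > G or k_times > T:
        raise TriclusterError("cluster counts cannot exceed the axis lengths")
    rng = rng if rng is not None else np.random.default_rng()
    courses = np.nanmean(tensor.nan_values, axis=1) if not tensor.complete else tensor.values.mean(axis=1)
    courses = np.where(np.isnan(courses), np.nanmean(courses), courses)
    best = np.inf
    for _ in range(repeats):
        km = KMeans(
            n_clusters=k_genes,
            n_init=1,
            max_iter=50,
            random_state=int(rng.integers(2**31)),
        )
        labels = km.fit_predict(courses)
        j = int(rng.integers(C))
        for c in range(k_genes):
            members = np.flatnonzero(labels == c)
            if members.size < 2:
                continue
            plane = tensor.nan_values[members, j, :]
            feats = np.where(np.isnan(plane), np.nanmean(plane), plane).T
            kt = min(k_times, T)
            tkm = KMeans(
                n_clusters=kt,
                n_init=1,
                max_iter=50,
                random_state=int(rng.integers(2**31)),
            )
            tlabels = tkm.fit_predict(feats)
            for tc in range(kt):
                times = np.flatnonzero(tlabels == tc)
                if times.size < 2:
                    continue  # single-column submatrices have MSR 0 by construction
                try:
                    msr = _msr_from_indices(tensor, members, np.array([j]), times)
                except TriclusterError:
                    continue
                best = min(best, msr)
    if not np.isfinite(best):
        raise TriclusterError("no eligible submatrix; increase repeats or cluster sizes")
    return float(best)


# ---------------------------------------------------------------------------
# Replicate distances
# ---------------------------------------------------------------------------

def replicate_distance_summary(
    tensor: ExpressionTensor, tric: Tricluster
) -> tuple[float, float]:
    """Mean pairwise Euclidean distance between replicate expression profiles.

    Profiles are restricted to the tricluster's genes and time points.
    Returns ``(clustered_mean, all_mean)``: the average over the member
    sample pairs and over all sample pairs of the tensor.  Distances are
    computed over cells observed in both profiles.
    """
    if len(tric.sample_idx) < 2 or tensor.n_samples < 2:
        raise TriclusterError("replicate distances require at least two samples")
    sub = tensor.nan_values[np.ix_(tric.gene_idx, range(tensor.n_samples), tric.time_idx)]
    flat = sub.transpose(1, 0, 2).reshape(tensor.n_samples, -1)

    def _mean_pairwise(indices) -> float:
        dists = []
        for a in range(len(indices)):
            for b in range(a + 1, len(indices)):
                x, y = flat[indices[a]], flat[indices[b]]
                common = ~(np.isnan(x) | np.isnan(y))
                if not common.any():
                    continue
                d = x[common] - y[common]
                dists.append(float(np.sqrt((d * d).sum())))
        if not dists:
            raise TriclusterError("no sample pair shares an observed cell")
        return float(np.mean(dists))

    clustered = _mean_pairwise(list(tric.sample_idx))
    overall = _mean_pairwise(list(range(tensor.n_samples)))
    return clustered, overall
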