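"""Evaluation statistics: affirmation, TD, SDB, enrichment, hit scores,
delta estimation and replicate distances."""

import math

import numpy as np
import pytest

from emoatrimax import (
    AnnotationCollection,
    ExpressionTensor,
    Tricluster,
    TriclusterSet,
    affirmation_score,
    enrich_gene_sets,
    estimate_delta,
    hit_score,
    hit_score_significance,
    replicate_distance_summary,
    sdb_score,
    tricluster_diffusion,
)
from emoatrimax.exceptions import TriclusterError
from emoatrimax.metrics import EnrichedTerm

from conftest import embed_block, tensor_from_values


def make_set(trics, G=100, C=6, T=8):
    return TriclusterSet(
        triclusters=tuple(
            Tricluster(tuple(sorted(I)), tuple(sorted(J)), tuple(sorted(K)), 0.0,
                       len(I) * len(J) * len(K))
            for I, J, K in trics
        ),
        gene_ids=tuple(f"g{i}" for i in range(G)),
        sample_ids=tuple(f"s{j}" for j in range(C)),
        time_ids=tuple(f"t{k}" for k in range(T)),
    )


def random_set(rng, n, G=100, C=6, T=8):
    trics = []
    for _ in range(n):
        I = rng.choice(G, size=rng.integers(2, 20), replace=False)
        J = rng.choice(C, size=rng.integers(1, C + 1), replace=False)
        K = rng.choice(T, size=rng.integers(2, T + 1), replace=False)
        trics.append((list(I), list(J), list(K)))
    return make_set(trics, G, C, T)


def affirmation_oracle(implanted, recovered):
    """All-pairs Jaccard maxima, averaged over the recovered set."""

    def jac(a, b):
        return len(a & b) / len(a | b)

    comps = [0.0, 0.0, 0.0]
    for r in range(len(recovered)):
        rs = recovered.label_sets(r)
        for ax in range(3):
            comps[ax] += max(jac(rs[ax], implanted.label_sets(i)[ax])
                             for i in range(len(implanted)))
    comps = [c / len(recovered) for c in comps]
    return math.sqrt(comps[0] * comps[1] * comps[2])


class TestAffirmationScore:
    def test_identity_is_exactly_one(self, rng):
        for trial in range(10):
            s = random_set(rng, int(rng.integers(1, 6)))
            assert affirmation_score(s, s).overall == 1.0

    def test_disjoint_sets_score_zero(self):
        a = make_set([(range(5), range(2), range(3))])
        b = make_set([(range(10, 15), range(3, 5), range(4, 7))])
        assert affirmation_score(a, b).overall == 0.0

    def test_hand_example(self):
        implanted = make_set([([0, 1, 2, 3], [0, 1], [0, 1])])
        recovered = make_set([([0, 1], [0, 1], [0, 1])])
        report = affirmation_score(implanted, recovered)
        assert report.gene_component == pytest.approx(0.5)
        assert report.sample_component == 1.0
        assert report.time_component == 1.0
        assert report.overall == pytest.approx(math.sqrt(0.5))

    def test_components_bounded_and_squared_identity(self, rng):
        a, b = random_set(rng, 4), random_set(rng, 3)
        r = affirmation_score(a, b)
        for c in (r.overall, r.gene_component, r.sample_component, r.time_component):
            assert 0.0 <= c <= 1.0
        assert r.overall**2 == pytest.approx(
            r.gene_component * r.sample_component * r.time_component
        )

    def test_agrees_with_brute_force_oracle(self, rng):
        for trial in range(10):
            a = random_set(rng, int(rng.integers(1, 6)))
            b = random_set(rng, int(rng.integers(1, 6)))
            assert affirmation_score(a, b).overall == pytest.approx(
                affirmation_oracle(a, b), abs=1e-12
            )

    def test_empty_set_rejected(self, rng):
        s = random_set(rng, 2)
        empty = TriclusterSet((), s.gene_ids, s.sample_ids, s.time_ids)
        with pytest.raises(TriclusterError):
            affirmation_score(empty, s)


class TestTriclusterDiffusion:
    def test_values(self):
        assert tricluster_diffusion(Tricluster((0,), (0,), (0,), 0.0, 1)) == 0.0
        assert tricluster_diffusion(
            Tricluster((0,), (0,), (0,), 0.05, 100)
        ) == pytest.approx(5e-4)

    def test_monotone_in_volume(self):
        small = Tricluster((0,), (0,), (0,), 0.05, 10)
        large = Tricluster((0,), (0,), (0,), 0.05, 100)
        assert tricluster_diffusion(large) < tricluster_diffusion(small)


class TestSDB:
    def make_noisy(self, rng):
        values = rng.uniform(-2, 2, size=(60, 6, 8))
        embed_block(values, range(15), range(3), range(4), rng)
        tensor = tensor_from_values(values + rng.normal(0, 0.1, size=values.shape))
        tric = Tricluster.from_indices(tensor, range(15), range(3), range(4))
        return tensor, tric

    def test_embedded_pattern_scores_positive(self, rng):
        tensor, tric = self.make_noisy(rng)
        tset = TriclusterSet((tric,), tensor.gene_ids, tensor.sample_ids, tensor.time_ids)
        assert sdb_score(tensor, tset, r=30, rng=rng) > 0

    def test_zero_msr_triclusters_skipped(self, rng):
        values = rng.uniform(-2, 2, size=(20, 4, 4))
        embed_block(values, range(5), range(2), range(3), rng)
        tensor = tensor_from_values(values)
        perfect = Tricluster.from_indices(tensor, range(5), range(2), range(3))
        tset = TriclusterSet((perfect,), tensor.gene_ids, tensor.sample_ids, tensor.time_ids)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(sdb_score(tensor, tset, r=5, rng=rng))

    def test_invariant_to_gene_labels(self, rng):
        tensor, tric = self.make_noisy(rng)
        relabeled = ExpressionTensor(
            tensor.values,
            tuple(f"x{i}" for i in range(60)),
            tensor.sample_ids,
            tensor.time_ids,
        )
        a = sdb_score(tensor, [tric], r=20, rng=np.random.default_rng(5))
        b = sdb_score(relabeled, [tric], r=20, rng=np.random.default_rng(5))
        assert a == b


def hypergeom_tail_oracle(M, n, N, k):
    """P(X >= k) by exhaustive enumeration over the support."""
    total = math.comb(M, N)
    return sum(
        math.comb(n, j) * math.comb(M - n, N - j)
        for j in range(k, min(n, N) + 1)
    ) / total


class TestEnrichment:
    def annotations(self):
        universe = frozenset(f"g{i}" for i in range(18))
        sets = {
            "A": frozenset({"g0", "g1", "g2", "g3"}),
            "B": frozenset({"g4", "g5"}),
            "C": frozenset(f"g{i}" for i in range(10, 18)),
        }
        return AnnotationCollection(sets=sets, universe=universe)

    def test_pvalues_match_enumeration_oracle(self):
        coll = self.annotations()
        genes = ["g0", "g1", "g2", "g4"]
        terms = enrich_gene_sets(genes, coll, alpha=1.0)
        by_name = {t.name: t for t in terms}
        M, N = 18, 4
        assert by_name["A"].p_value == pytest.approx(
            hypergeom_tail_oracle(M, 4, N, 3), rel=1e-9
        )
        assert by_name["B"].p_value == pytest.approx(
            hypergeom_tail_oracle(M, 2, N, 1), rel=1e-9
        )

    def test_matching_set_is_enriched(self):
        coll = self.annotations()
        terms = enrich_gene_sets(["g0", "g1", "g2", "g3"], coll, alpha=0.05)
        assert [t.name for t in terms] == ["A"]
        assert terms[0].overlap == frozenset({"g0", "g1", "g2", "g3"})

    def test_disjoint_set_not_enriched(self):
        coll = self.annotations()
        terms = enrich_gene_sets(["g6", "g7"], coll, alpha=0.05)
        assert terms == []

    def test_alpha_one_returns_all_overlapping_sorted(self):
        coll = self.annotations()
        terms = enrich_gene_sets(["g0", "g4", "g10"], coll, alpha=1.0)
        assert {t.name for t in terms} == {"A", "B", "C"}
        ps = [t.p_value for t in terms]
        assert ps == sorted(ps)


class TestHitScore:
    def term(self, genes):
        return EnrichedTerm("t", frozenset(genes), 0.01, 0.01)

    def test_max_overlap_ratio(self):
        genes = [f"g{i}" for i in range(10)]
        enriched = [self.term(genes[:3]), self.term(genes[:5]), self.term(genes[:2])]
        assert hit_score(genes, enriched) == pytest.approx(0.5)

    def test_full_coverage_and_empty(self):
        genes = ["a", "b"]
        assert hit_score(genes, [self.term(genes)]) == 1.0
        assert hit_score(genes, []) == 0.0


class TestHitScoreSignificance:
    def annotations(self, rng, n_sets=8, universe_size=60, set_size=6):
        universe = [f"g{i}" for i in range(universe_size)]
        sets = {
            f"set{s}": frozenset(
                universe[i] for i in rng.choice(universe_size, set_size, replace=False)
            )
            for s in range(n_sets)
        }
        return AnnotationCollection(sets=sets, universe=frozenset(universe))

    def test_random_gene_list_is_not_significant(self, rng):
        coll = self.annotations(rng)
        genes = [f"g{i}" for i in rng.choice(60, 8, replace=False)]
        p = hit_score_significance(genes, coll, n_random=30, rng=rng)
        assert p > 0.01

    def test_annotation_matching_list_is_significant(self, rng):
        coll = self.annotations(rng)
        genes = sorted(coll.sets["set0"])
        p = hit_score_significance(genes, coll, n_random=50, rng=rng)
        assert p < 0.05

    def test_degenerate_identical_scores_give_one(self, rng):
        universe = frozenset(f"g{i}" for i in range(10))
        coll = AnnotationCollection(sets={}, universe=universe)
        p = hit_score_significance(["g0", "g1"], coll, n_random=10, rng=rng)
        assert p == 1.0


class TestEstimateDelta:
    def test_embedded_perfect_block_drives_delta_to_zero(self, rng):
        values = rng.uniform(-2, 2, size=(30, 4, 8))
        embed_block(values, range(15), range(4), range(8), rng)
        tensor = tensor_from_values(values)
        delta = estimate_delta(tensor, repeats=30, rng=rng)
        assert delta < 1e-6

    def test_deterministic_given_seed(self, rng):
        tensor = tensor_from_values(rng.normal(size=(20, 3, 6)))
        a = estimate_delta(tensor, repeats=3, rng=np.random.default_rng(1))
        b = estimate_delta(tensor, repeats=3, rng=np.random.default_rng(1))
        assert a == b

    def test_monotone_in_repeats_for_nested_seeds(self, rng):
        tensor = tensor_from_values(rng.normal(size=(20, 3, 6)))
        few = estimate_delta(tensor, repeats=2, rng=np.random.default_rng(2))
        many = estimate_delta(tensor, repeats=6, rng=np.random.default_rng(2))
        assert many <= few

    def test_oversized_cluster_count_rejected(self, rng):
        tensor = tensor_from_values(rng.normal(size=(10, 3, 4)))
        with pytest.raises(TriclusterError):
            estimate_delta(tensor, k_genes=50, rng=rng)


class TestReplicateDistances:
    def test_identical_samples_give_zero(self):
        values = np.tile(np.arange(12.0).reshape(3, 1, 4), (1, 4, 1))
        tensor = tensor_from_values(values)
        tric = Tricluster.from_indices(tensor, range(3), [0, 1], range(4))
        assert replicate_distance_summary(tensor, tric) == (0.0, 0.0)

    def test_shifted_outside_sample_raises_overall_mean(self):
        values = np.tile(np.arange(12.0).reshape(3, 1, 4), (1, 3, 1))
        c = 2.0
        values[:, 2, :] += c  # outside sample shifted by a constant
        tensor = tensor_from_values(values)
        tric = Tricluster.from_indices(tensor, range(3), [0, 1], range(4))
        clustered, overall = replicate_distance_summary(tensor, tric)
        assert clustered == 0.0
        m = 12  # cells per profile
        expected = (0.0 + 2 * c * math.sqrt(m)) / 3  # pairs: (0,1), (0,2), (1,2)
        assert overall == pytest.approx(expected)

    def test_member_samples_tighter_on_embedded_pattern(self, rng):
        values = rng.uniform(-2, 2, size=(30, 6, 6))
        embed_block(values, range(10), [0, 1, 2], range(4), rng)
        tensor = tensor_from_values(values)
        tric = Tricluster.from_indices(tensor, range(10), [0, 1, 2], range(4))
        clustered, overall = replicate_distance_summary(tensor, tric)
        assert clustered <= overall

    def test_single_sample_rejected(self, rng):
        tensor = tensor_from_values(rng.normal(size=(4, 3, 4)))
        tric = Tricluster.from_indices(tensor, range(4), [0], range(4))
        with pytest.raises(TriclusterError):
            replicate_distance_summary(tensor, tric)
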