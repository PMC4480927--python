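"""Greedy repair: node deletion, node addition and the composed repair."""

import numpy as np
import pytest

from emoatrimax import (
    LocalSearchConfig,
    Tricluster,
    compute_msr,
    multiple_node_deletion,
    node_addition,
    repair,
    single_node_deletion,
)

from conftest import embed_block, full_tricluster, random_shifting_params, tensor_from_values


def perfect_tensor(shape, rng):
    return tensor_from_values(random_shifting_params(shape, rng).block())


class TestMultipleNodeDeletion:
    def test_perfect_tricluster_unchanged(self, rng):
        tensor = perfect_tensor((5, 3, 3), rng)
        tric = full_tricluster(tensor)
        out = multiple_node_deletion(tensor, tric, LocalSearchConfig(delta=0.01))
        assert out.key == tric.key

    def test_outlier_gene_removed(self, rng):
        # perfect 4x3x3 block plus one incoherent gene; with the small-axis
        # guard disabled the outlier must be the only node dropped
        values = np.empty((5, 3, 3))
        values[:4] = random_shifting_params((4, 3, 3), rng).block()
        values[4] = rng.normal(scale=10.0, size=(3, 3))
        tensor = tensor_from_values(values)
        cfg = LocalSearchConfig(delta=1e-6, multiple_deletion_min_axis=0)
        out = multiple_node_deletion(tensor, full_tricluster(tensor), cfg)
        assert out.gene_idx == (0, 1, 2, 3)
        assert out.msr <= cfg.delta
        # cross-check: of all single-gene removals, dropping the outlier
        # minimizes the MSR
        removal_msrs = [
            Tricluster.from_indices(tensor, [g for g in range(5) if g != drop],
                                    range(3), range(3)).msr
            for drop in range(5)
        ]
        assert int(np.argmin(removal_msrs)) == 4

    def test_floor_respected(self, rng):
        tensor = tensor_from_values(rng.normal(size=(2, 1, 3)))
        tric = full_tricluster(tensor)
        cfg = LocalSearchConfig(delta=1e-12, min_times=3, multiple_deletion_min_axis=0)
        out = multiple_node_deletion(tensor, tric, cfg)
        assert out.shape == (2, 1, 3)  # nothing below the floors is deleted


class TestSingleNodeDeletion:
    def test_perfect_tricluster_unchanged(self, rng):
        tensor = perfect_tensor((5, 3, 3), rng)
        tric = full_tricluster(tensor)
        out = single_node_deletion(tensor, tric, LocalSearchConfig(delta=0.01))
        assert out.key == tric.key

    def test_residue_carrier_removed_first(self, rng):
        values = random_shifting_params((3, 3, 3), rng).block()
        values[1] += rng.normal(scale=5.0, size=(3, 3))  # gene 1 carries all residue
        tensor = tensor_from_values(values)
        out = single_node_deletion(
            tensor, full_tricluster(tensor), LocalSearchConfig(delta=1e-9)
        )
        assert out.gene_idx == (0, 2)
        assert out.msr <= 1e-9

    def test_tie_breaks_to_lowest_index(self, rng):
        # two identical noisy genes tie exactly; the lower index goes first
        noisy = rng.normal(scale=5.0, size=(3, 3))
        values = np.empty((4, 3, 3))
        values[2:] = random_shifting_params((2, 3, 3), rng).block()
        values[0] = noisy
        values[1] = noisy
        tensor = tensor_from_values(values)
        cfg = LocalSearchConfig(delta=1e-9, min_genes=3)
        out = single_node_deletion(tensor, full_tricluster(tensor), cfg)
        assert 0 not in out.gene_idx and 1 in out.gene_idx


class TestNodeAddition:
    def test_maximal_tricluster_is_fixed_point(self, rng):
        values = rng.uniform(-2, 2, size=(12, 4, 5))
        embed_block(values, range(6), range(3), range(4), rng)
        tensor = tensor_from_values(values)
        tric = Tricluster.from_indices(tensor, range(6), range(3), range(4))
        cfg = LocalSearchConfig(delta=1e-6)
        out = node_addition(tensor, tric, cfg)
        assert node_addition(tensor, out, cfg).key == out.key

    def test_seed_grows_to_full_pattern(self, rng):
        values = rng.uniform(-2, 2, size=(25, 4, 5))
        embed_block(values, range(10), range(3), range(3), rng)
        tensor = tensor_from_values(values)
        seed = Tricluster.from_indices(tensor, range(4), range(3), range(3))
        out = node_addition(tensor, seed, LocalSearchConfig(delta=1e-6))
        assert set(out.gene_idx) >= set(range(10))
        assert out.msr <= 1e-6

    def test_delta_property_preserved(self, rng):
        for trial in range(5):
            values = rng.uniform(-2, 2, size=(15, 4, 5))
            embed_block(values, range(5), range(3), range(3), rng)
            tensor = tensor_from_values(values)
            tric = Tricluster.from_indices(tensor, range(5), range(3), range(3))
            cfg = LocalSearchConfig(delta=1e-5)
            assert node_addition(tensor, tric, cfg).msr <= cfg.delta + 1e-12


class TestRepair:
    def make_tensor(self, rng, shape=(40, 6, 8), block=(12, 3, 4)):
        values = rng.uniform(-2, 2, size=shape)
        I = list(range(block[0]))
        J = list(range(block[1]))
        K = list(range(block[2]))
        embed_block(values, I, J, K, rng)
        return tensor_from_values(values), (tuple(I), tuple(J), tuple(K))

    def test_feasible_output_satisfies_delta(self, rng):
        tensor, _ = self.make_tensor(rng)
        cfg = LocalSearchConfig(delta=1e-4, min_times=3)
        for trial in range(8):
            genes = np.flatnonzero(rng.random(40) < 0.5)
            samples = np.flatnonzero(rng.random(6) < 0.6)
            times = np.flatnonzero(rng.random(8) < 0.6)
            if genes.size < 2 or samples.size < 1 or times.size < 3:
                continue
            tric = Tricluster.from_indices(tensor, genes, samples, times)
            rr = repair(tensor, tric, cfg)
            if rr.feasible:
                assert rr.tricluster.msr <= cfg.delta
                assert compute_msr(tensor, rr.tricluster) <= cfg.delta

    def test_idempotent(self, rng):
        tensor, _ = self.make_tensor(rng)
        cfg = LocalSearchConfig(delta=1e-4, min_times=3)
        tric = Tricluster.from_indices(tensor, range(0, 30), range(5), range(6))
        once = repair(tensor, tric, cfg)
        twice = repair(tensor, once.tricluster, cfg)
        assert twice.tricluster.key == once.tricluster.key

    def test_perfect_candidate_never_shrunk(self, rng):
        tensor, (I, J, K) = self.make_tensor(rng)
        cfg = LocalSearchConfig(delta=1e-6, min_times=3)
        tric = Tricluster.from_indices(tensor, I, J, K)
        rr = repair(tensor, tric, cfg)
        assert rr.feasible
        assert set(rr.tricluster.gene_idx) >= set(I)
        assert set(rr.tricluster.sample_idx) >= set(J)
        assert set(rr.tricluster.time_idx) >= set(K)

    def test_recovers_pattern_from_overlapping_seeds(self, rng):
        """A seed containing the embedded pattern plus background nodes is
        repaired to exactly the pattern's membership (10 seeded instances)."""
        hits = 0
        for trial in range(10):
            tensor, (I, J, K) = self.make_tensor(rng, block=(15, 3, 5))
            extra_g = rng.choice(np.setdiff1d(np.arange(40), I), size=6, replace=False)
            extra_s = rng.choice(np.setdiff1d(np.arange(6), J), size=1, replace=False)
            extra_t = rng.choice(np.setdiff1d(np.arange(8), K), size=2, replace=False)
            seed = Tricluster.from_indices(
                tensor,
                list(I) + list(extra_g),
                list(J) + list(extra_s),
                list(K) + list(extra_t),
            )
            rr = repair(tensor, seed, LocalSearchConfig(delta=1e-6, min_times=3))
            if rr.feasible and set(rr.tricluster.gene_idx) == set(I):
                hits += 1
        assert hits == 10

    def test_infeasible_at_floor_is_flagged(self, rng):
        tensor = tensor_from_values(rng.normal(scale=5.0, size=(2, 1, 3)))
        cfg = LocalSearchConfig(delta=1e-12, min_times=3)
        rr = repair(tensor, full_tricluster(tensor), cfg)
        assert not rr.feasible
        assert rr.tricluster.shape == (2, 1, 3)
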