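"""Synthetic shifting-pattern benchmark tensors.

Generates random background tensors with embedded perfect (or noisy)
shifting triclusters and records the implanted index sets as ground
truth.  The named presets reproduce the geometries of the four standard
artificial benchmark designs:

=======  ==================  =============================  ===========
preset   tensor (G x C x T)  implanted blocks               noise scope
=======  ==================  =============================  ===========
AD1      1000 x 5 x 4        100x4x4, 80x4x4, 60x4x4        blocks
AD2      200 x 10 x 10       3 blocks of 50x3x3             tensor
AD3a     200 x 10 x 20       30x3x8, 30x3x6, 30x3x4         tensor
AD3b     200 x 10 x 25       30x3x8, 30x3x6, 30x3x4         tensor
AD3c     200 x 10 x 30       30x3x8, 30x3x6, 30x3x4         tensor
AD4      200 x 10 x 20       30x3x8, 30x3x6, 30x3x4 (+NA)   tensor
=======  ==================  =============================  ===========

Gaussian noise with standard deviation ``sigma`` is added either to the
block cells only ("blocks", the AD1 design) or to the whole tensor
("tensor", AD2-AD4).  AD4 additionally masks a random fraction of all
cells (0.5-2 % in the benchmark) as missing.

Background cells are i.i.d. uniform on [-2, 2] and the shifting
parameters (Gamma and the per-gene/sample/time offsets) are standard
normal, so implanted blocks are markedly more coherent than background
while spanning a comparable dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .core import ExpressionTensor, ShiftingParameters, Tricluster, TriclusterSet
from .exceptions import TriclusterError

__all__ = [
    "EmbeddingSpec",
    "make_shifting_block",
    "generate",
    "preset",
    "PRESET_GEOMETRIES",
    "BENCHMARK_DELTAS",
]

PRESET_GEOMETRIES = {
    "AD1": ((1000, 5, 4), ((100, 4, 4), (80, 4, 4), (60, 4, 4)), "blocks", ("genes",)),
    "AD2": ((200, 10, 10), ((50, 3, 3),) * 3, "tensor", ("genes", "samples", "times")),
    "AD3a": ((200, 10, 20), ((30, 3, 8), (30, 3, 6), (30, 3, 4)), "tensor", ("genes", "samples", "times")),
    "AD3b": ((200, 10, 25), ((30, 3, 8), (30, 3, 6), (30, 3, 4)), "tensor", ("genes", "samples", "times")),
    "AD3c": ((200, 10, 30), ((30, 3, 8), (30, 3, 6), (30, 3, 4)), "tensor", ("genes", "samples", "times")),
    "AD4": ((200, 10, 20), ((30, 3, 8), (30, 3, 6), (30, 3, 4)), "tensor", ("genes", "samples", "times")),
}

# MSR ceilings used with the benchmark designs at each noise level
# (obtained with the randomized estimation heuristic; see estimate_delta).
BENCHMARK_DELTAS = {
    "AD1": {0.0: 0.0002, 0.1: 0.025, 0.3: 0.115, 0.5: 0.26, 0.7: 0.49, 0.9: 0.85},
    "AD2": {0.0: 0.00002, 0.1: 0.045, 0.3: 0.06, 0.5: 0.29, 0.7: 0.59, 0.9: 0.8},
    "AD3a": {0.0: 0.0002},
    "AD3b": {0.0: 0.02},
    "AD3c": {0.0: 0.02},
    "AD4": {0.0: 0.02},
}


@dataclass(frozen=True)
class EmbeddingSpec:
    """Full recipe for one synthetic tensor (a pure function of its fields)."""

    tensor_shape: tuple[int, int, int]
    tricluster_shapes: tuple[tuple[int, int, int], ...]
    noise_sigma: float = 0.0
    missing_fraction: float = 0.0
    background_range: tuple[float, float] = (-2.0, 2.0)
    shift_sd: float = 1.0
    gamma_sd: float = 1.0
    noise_scope: str = "tensor"
    disjoint_axes: tuple[str, ...] = ("genes", "samples", "times")
    block_indices: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        G, C, T = self.tensor_shape
        shapes = tuple(tuple(int(x) for x in s) for s in self.tricluster_shapes)
        object.__setattr__(self, "tricluster_shapes", shapes)
        for g, c, t in shapes:
            if g > G or c > C or t > T or min(g, c, t) < 1:
                raise TriclusterError("tricluster shape does not fit inside the tensor")
        if self.noise_sigma < 0:
            raise TriclusterError("noise_sigma must be nonnegative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise TriclusterError("missing_fraction must lie in [0, 1)")
        if self.noise_scope not in ("tensor", "blocks"):
            raise TriclusterError("noise_scope must be 'tensor' or 'blocks'")
        limits = dict(zip(("genes", "samples", "times"), (G, C, T)))
        if self.block_indices is None:
            for ax_name, ax in zip(("genes", "samples", "times"), range(3)):
                if ax_name in self.disjoint_axes:
                    if sum(s[ax] for s in shapes) > limits[ax_name]:
                        raise TriclusterError(
                            f"blocks cannot be placed disjointly on the {ax_name} axis"
                        )


def make_shifting_block(
    shape: tuple[int, int, int],
    gamma: float,
    alpha: Sequence[float],
    beta: Sequence[float],
    eta: Sequence[float],
) -> np.ndarray:
    """Perfect shifting block ``m_ijk = gamma + alpha_i + beta_j + eta_k``."""
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if (alpha.shape, beta.shape, eta.shape) != ((shape[0],), (shape[1],), (shape[2],)):
        raise TriclusterError("shift vector lengths must match the block shape")
    return ShiftingParameters(gamma, alpha, beta, eta).block()


def _draw_axis(rng, n, sizes, disjoint):
    """Index subsets per block along one axis, disjoint or independent."""
    if disjoint:
        perm = rng.permutation(n)
        out, at = [], 0
        for s in sizes:
            out.append(np.sort(perm[at : at + s]))
            at += s
        return out
    return [np.sort(rng.choice(n, size=s, replace=False)) for s in sizes]


def generate(spec: EmbeddingSpec) -> tuple[ExpressionTensor, TriclusterSet]:
    """Materialize a spec into a tensor plus its ground-truth tricluster set.

    Deterministic in ``spec`` (including the seed).  Ground-truth MSR is
    computed on the finished tensor, i.e. it reflects the requested noise
    and missingness.
    """
    rng = np.random.default_rng(spec.seed)
    G, C, T = spec.tensor_shape
    lo, hi = spec.background_range
    values = rng.uniform(lo, hi, size=(G, C, T))

    if spec.block_indices is not None:
        blocks = [
            tuple(np.asarray(sorted(set(ix)), dtype=int) for ix in blk)
            for blk in spec.block_indices
        ]
        seen = set()
        for I, J, K in blocks:
            for cell in ((i, j, k) for i in I for j in J for k in K):
                if cell in seen:
                    raise TriclusterError("explicit blocks collide on a tensor cell")
                seen.add(cell)
    else:
        sizes = list(zip(*spec.tricluster_shapes))
        gene_sets = _draw_axis(rng, G, sizes[0], "genes" in spec.disjoint_axes)
        sample_sets = _draw_axis(rng, C, sizes[1], "samples" in spec.disjoint_axes)
        time_sets = _draw_axis(rng, T, sizes[2], "times" in spec.disjoint_axes)
        blocks = list(zip(gene_sets, sample_sets, time_sets))

    block_mask = np.zeros((G, C, T), dtype=bool)
    for I, J, K in blocks:
        params = ShiftingParameters(
            gamma=float(rng.normal(0.0, spec.gamma_sd)),
            alpha=rng.normal(0.0, spec.shift_sd, size=len(I)),
            beta=rng.normal(0.0, spec.shift_sd, size=len(J)),
            eta=rng.normal(0.0, spec.shift_sd, size=len(K)),
        )
        values[np.ix_(I, J, K)] = params.block()
        block_mask[np.ix_(I, J, K)] = True

    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=(G, C, T))
        if spec.noise_scope == "blocks":
            values = np.where(block_mask, values + noise, values)
        else:
            values = values + noise

    mask = None
    if spec.missing_fraction > 0:
        mask = rng.random((G, C, T)) >= spec.missing_fraction

    tensor = ExpressionTensor(
        values=values,
        gene_ids=tuple(f"g{i:04d}" for i in range(G)),
        sample_ids=tuple(f"s{j:02d}" for j in range(C)),
        time_ids=tuple(f"t{k:02d}" for k in range(T)),
        mask=mask,
    )
    truth = TriclusterSet(
        triclusters=tuple(
            Tricluster.from_indices(tensor, I, J, K) for I, J, K in blocks
        ),
        gene_ids=tensor.gene_ids,
        sample_ids=tensor.sample_ids,
        time_ids=tensor.time_ids,
        provenance={"generator": asdict(spec)},
    )
    return tensor, truth


def preset(
    name: str,
    sigma: float = 0.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> EmbeddingSpec:
    """Benchmark-faithful geometry for a named artificial dataset."""
    if name not in PRESET_GEOMETRIES:
        raise TriclusterError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_GEOMETRIES)}"
        )
    shape, blocks, scope, disjoint = PRESET_GEOMETRIES[name]
    return EmbeddingSpec(
        tensor_shape=shape,
        tricluster_shapes=blocks,
        noise_sigma=sigma,
        missing_fraction=missing_fraction,
        noise_scope=scope,
        disjoint_axes=disjoint,
        seed=seed,
    )
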