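import numpy as np
import pytest

from emoatrimax import ExpressionTensor, ShiftingParameters, Tricluster


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def tensor_from_values(values, mask=None):
    values = np.asarray(values, dtype=float)
    G, C, T = values.shape
    return ExpressionTensor(
        values=values,
        gene_ids=tuple(f"g{i}" for i in range(G)),
        sample_ids=tuple(f"s{j}" for j in range(C)),
        time_ids=tuple(f"t{k}" for k in range(T)),
        mask=mask,
    )


def random_shifting_params(shape, rng):
    return ShiftingParameters(
        gamma=float(rng.normal()),
        alpha=rng.normal(size=shape[0]),
        beta=rng.normal(size=shape[1]),
        eta=rng.normal(size=shape[2]),
    )


def embed_block(values, I, J, K, rng):
    """Write a random perfect shifting block at the given indices."""
    params = ShiftingParameters(
        gamma=float(rng.normal()),
        alpha=rng.normal(size=len(I)),
        beta=rng.normal(size=len(J)),
        eta=rng.normal(size=len(K)),
    )
    values[np.ix_(I, J, K)] = params.block()
    return params


def full_tricluster(tensor):
    G, C, T = tensor.shape
    return Tricluster.from_indices(tensor, range(G), range(C), range(T))
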