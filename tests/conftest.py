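import numpy as np
import pytest

from tdfe.model import TensorFE
from tdfe.synthetic import default_study_spec, generate_dataset


@pytest.fixture(scope="session")
def study_fit():
    """Default planted-signal study dataset, fitted once per session.

    Returns (spec, matrices, ground truth, fitted results).
    """
    spec = default_study_spec(seed=1)
    matrices, truth = generate_dataset(spec)
    results = TensorFE.from_count_matrices(matrices, spec.sample_map()).fit()
    return spec, matrices, truth, results


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_tensor(rng, shape=(6, 4, 3, 2)):
    """Standardized random tensor for decomposition tests."""
    from tdfe.tensor import ExpressionTensor, standardize

    raw = rng.gamma(2.0, 50.0, size=shape)
    t = ExpressionTensor(
        values=raw,
        gene_ids=[f"g{i}" for i in range(shape[0])],
        tissue_names=[f"T{j}" for j in range(shape[1])],
        treatment_names=[f"D{k}" for k in range(shape[2])],
        replicate_labels=list(range(1, shape[3] + 1)),
    )
    return standardize(t, log_transform=False)
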