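import numpy as np
import pytest
from hypothesis import settings

import tlpca

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def benchmark():
    return tlpca.builtin_benchmark()


@pytest.fixture(scope="session")
def training_tensor(benchmark):
    return tlpca.encode_peptides(benchmark.training, benchmark.property_table)


@pytest.fixture(scope="session")
def testing_tensor(benchmark):
    return tlpca.encode_peptides(benchmark.testing, benchmark.property_table)


@pytest.fixture(scope="session")
def benchmark_fit(training_tensor):
    """One converged fit on the 90 training peptides, shared across tests."""
    return tlpca.fit(training_tensor, tlpca.SolverConfig())


@pytest.fixture
def tiny_table():
    return tlpca.PropertyTable(
        residues=("A", "C", "G"),
        property_names=("p1", "p2"),
        values=np.array([[1.0, 2.0], [3.0, -4.0], [0.5, 0.0]]),
    )


@pytest.fixture
def small_tensor():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(6, 3, 2))
    W = rng.normal(size=6)
    return tlpca.FragmentTensor(
        sample_ids=tuple(f"s{i}" for i in range(6)),
        fragment_labels=("f1", "f2", "f3"),
        property_names=("p1", "p2"),
        X=X,
        W=W,
    )
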