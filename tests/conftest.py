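import numpy as np
import pytest

from epicollect.dataio import GenotypeMatrix, PhenotypeVector, SimulatedDataset, TruthManifest


def make_dataset(values, labels, truth=None, prefix="G") -> SimulatedDataset:
    values = np.asarray(values)
    n, p = values.shape
    return SimulatedDataset(
        genotypes=GenotypeMatrix(
            values,
            feature_ids=tuple(f"{prefix}{j + 1}" for j in range(p)),
            sample_ids=tuple(f"S{i + 1}" for i in range(n)),
        ),
        phenotype=PhenotypeVector(np.asarray(labels)),
        truth=truth,
    )


def random_dataset(rng, n, p) -> SimulatedDataset:
    while True:  # need both classes present
        y = rng.integers(0, 2, size=n)
        if 0 < y.sum() < n:
            break
    return make_dataset(rng.integers(0, 3, size=(n, p)), y)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, 40, 6)


@pytest.fixture
def truth_ab():
    return TruthManifest(
        causal_ids=frozenset({"G1", "G2"}),
        model_name="toy",
        effect_structure=((("G1", "G2"), "case"),),
    )
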