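import numpy as np
import pytest

from pairfs import Dataset, EvalConfig, SyntheticSpec, generate


@pytest.fixture
def knn1():
    return EvalConfig(classifier="knn", params={"k": 1}, cv="loocv")


@pytest.fixture
def knn3():
    return EvalConfig(classifier="knn", params={"k": 3}, cv="loocv")


@pytest.fixture
def small_ds():
    """8 samples, 4 features: a perfect separator, a weak feature, noise."""
    rng = np.random.default_rng(42)
    sep = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    weak = sep * 0.8 + rng.normal(0, 0.6, 8)
    return Dataset(
        np.column_stack([sep, weak, rng.normal(size=8), rng.normal(size=8)]),
        ["A"] * 4 + ["B"] * 4,
        ["sep", "weak", "noise1", "noise2"],
    )


@pytest.fixture
def xor_ds():
    """Planted XOR pair among univariate and noise features, n=100."""
    spec = SyntheticSpec(n_samples=100, n_univariate=3, effect_size=1.0,
                         n_xor_pairs=1, n_noise=8, seed=11)
    return generate(spec)


def make_random_ds(n_samples, n_features, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array([f"c{i % n_classes}" for i in range(n_samples)])
    return Dataset(rng.normal(size=(n_samples, n_features)), labels,
                   [f"f{i}" for i in range(n_features)])
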