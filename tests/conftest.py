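import numpy as np
import pytest

import stressmir as sm

RNG_ALPHABET = "ACGU"


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNG_ALPHABET), size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def separated_matrix():
    """Strongly separated two-class PseKNC matrix (GC-rich vs AU-rich)."""
    result = sm.simulate(sm.SimSpec(n_per_class=40, effect=1.0, seed=11))
    return sm.encode_dataset(result.mature_manifest(), sm.PseKNCConfig(k_values=(2, 3)))


@pytest.fixture(scope="session")
def toy_matrix():
    """Tiny linearly separable matrix: feature 'f0' alone separates classes."""
    rng = np.random.default_rng(5)
    n = 20
    X = rng.normal(size=(n, 3))
    y = np.repeat([1, 0], n // 2)
    X[:, 0] = y * 4.0 + rng.normal(scale=0.1, size=n)
    return sm.FeatureMatrix(
        X,
        ["f0", "f1", "f2"],
        [f"r{i}" for i in range(n)],
        ["positive" if t else "negative" for t in y],
    )
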