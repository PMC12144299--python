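import numpy as np
import pytest

from seqtlboga.datasets import SyntheticSpec, make_synthetic
from seqtlboga.qpop import BinaryLearner, QubitLearner

DEFAULT_BOUNDS = ((0.01, 100.0), (0.01, 10.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bounds():
    return DEFAULT_BOUNDS


@pytest.fixture(scope="session")
def small_dataset():
    """150 samples, 6 features (2 informative, shift 1.5) — fast SVM fits."""
    ds, informative = make_synthetic(
        SyntheticSpec(
            n_samples=150, n_features=6, n_informative=2, mean_shift=1.5, seed=42
        )
    )
    return ds, informative


@pytest.fixture(scope="session")
def separable_dataset():
    """Perfectly separated two-cluster data (class means +/-5, unit variance)."""
    ds, informative = make_synthetic(
        SyntheticSpec(
            n_samples=120,
            n_features=4,
            n_informative=2,
            mean_shift=10.0,
            class_fraction_positive=0.5,
            seed=7,
        )
    )
    return ds, informative


def make_qubit(beta: np.ndarray, c=1.0, sigma=1.0) -> QubitLearner:
    beta = np.asarray(beta, dtype=float)
    alpha = np.sqrt(np.clip(1.0 - beta**2, 0.0, 1.0))
    return QubitLearner(alpha, beta, c, sigma)


def make_binary(bits, c=1.0, sigma=1.0) -> BinaryLearner:
    return BinaryLearner(np.asarray(list(bits), dtype=np.int8), c, sigma)
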