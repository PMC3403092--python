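import numpy as np
import pytest

from lpfs.io_profiles import GroupedDataset, ProfileMatrix
from lpfs.synthetic import SyntheticSpec, generate, planted_spec


@pytest.fixture
def tiny4() -> GroupedDataset:
    """Two case samples at 0 and 2, two controls at 10 and 12, one feature."""
    return GroupedDataset(
        T=np.array([[0.0], [2.0]]),
        F=np.array([[10.0], [12.0]]),
        feature_ids=("f0",),
    )


@pytest.fixture
def small_profile() -> ProfileMatrix:
    return ProfileMatrix(
        values=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
        sample_ids=("s1", "s2"),
        feature_ids=("f1", "f2", "f3"),
        ppm=np.array([5.0, 4.0, 4.7]),
    )


@pytest.fixture
def separated_ds() -> GroupedDataset:
    """Well-separated groups: five 6-sigma markers among 30 features."""
    ds, _ = generate(
        planted_spec(seed=7, n_features=30, m1=5, m2=5, n_planted=5, shift=6.0)
    )
    return ds


def random_grouped(rng: np.random.Generator, m1: int, m2: int, n: int) -> GroupedDataset:
    return GroupedDataset(
        T=rng.normal(1.0, 0.3, size=(m1, n)) ** 2,
        F=rng.normal(1.0, 0.3, size=(m2, n)) ** 2,
        feature_ids=tuple(f"f{i}" for i in range(n)),
    )
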