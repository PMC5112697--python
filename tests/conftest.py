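import numpy as np
import pytest

from pdmedit.dataset_io import Dataset, SyntheticConfig, generate_synthetic


@pytest.fixture
def separable_dataset() -> Dataset:
    """Two tight, far-apart clusters; every editing/classification step
    should be perfect on this fixture."""
    rng = np.random.default_rng(7)
    n = 20
    X0 = rng.normal(0.0, 0.1, size=(n, 2))
    X1 = rng.normal(10.0, 0.1, size=(n, 2))
    ids = np.array(
        [f"H{i % 4}" for i in range(n)] + [f"P{i % 4}" for i in range(n)],
        dtype=object,
    )
    return Dataset(
        subject_ids=ids,
        X=np.vstack([X0, X1]),
        y=np.r_[np.zeros(n, int), np.ones(n, int)],
    )


@pytest.fixture
def contaminated_dataset() -> Dataset:
    """Small subject-clustered dataset with contaminated samples flagged."""
    return generate_synthetic(
        SyntheticConfig(
            subjects_per_class=4,
            samples_per_subject=8,
            d=4,
            class_separation=2.0,
            subject_sd=0.5,
            noise_sd=0.5,
            contamination=0.25,
            seed=11,
        )
    )


def gaussian_1d_dataset(seed: int, n_per_class: int = 400) -> Dataset:
    """Two overlapping 1-D Gaussians N(0,1) vs N(2,1); Bayes error Phi(-1)."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(n_per_class, 1)),
            rng.normal(2.0, 1.0, size=(n_per_class, 1)),
        ]
    )
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    ids = np.array([f"s{i}" for i in range(2 * n_per_class)], dtype=object)
    return Dataset(subject_ids=ids, X=X, y=y)
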