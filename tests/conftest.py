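import numpy as np
import pytest

from atlasboot import Atlas, IntensityImage, LabelImage


def make_atlas(aid, labels, intensity=None, voxel_size=(1.0, 1.0, 1.0)):
    labels = np.asarray(labels)
    if intensity is None:
        intensity = labels.astype(float)
    return Atlas(
        id=aid,
        intensity=IntensityImage(np.asarray(intensity, dtype=float), voxel_size),
        labels=LabelImage(labels.astype(np.int32), voxel_size),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design(rng):
    """A well-conditioned random WLS problem (n=30, p=3 incl. intercept)."""
    n = 30
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    beta = np.array([1.0, -2.0, 0.5])
    w = rng.uniform(0.2, 3.0, n)
    y = X @ beta + rng.normal(size=n) / np.sqrt(w)
    return X, y, w
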