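import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from emfdeeg import EntropyFeaturizer, SynthConfig, generate_dataset
from emfdeeg.entropy_features import split_features_meta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_strong_features():
    """Entropy feature matrix of a small strong-effect synthetic dataset.

    Six subjects, 24 s per condition under the 14-channel montage: 72
    four-second segments, 3 modes per channel.  Shared across tests to
    keep the suite fast.
    """
    cfg = SynthConfig(n_subjects=6, rest_duration_s=24.0, task_duration_s=24.0,
                      seed=7)
    segments = generate_dataset(cfg)
    matrix = EntropyFeaturizer(n_modes=3).fit_transform(segments)
    return matrix


@pytest.fixture(scope="session")
def small_strong_Xy(small_strong_features):
    feats, meta = split_features_meta(small_strong_features)
    return feats, meta["condition"].to_numpy()


@pytest.fixture(scope="session")
def gaussian_blobs():
    """Well-separated two-class Gaussian features (trivially learnable)."""
    rng = np.random.default_rng(0)
    n = 50
    X = np.vstack([rng.normal(0.0, 1.0, (n, 4)), rng.normal(10.0, 1.0, (n, 4))])
    y = np.array(["rest"] * n + ["task"] * n)
    perm = rng.permutation(2 * n)
    return X[perm], y[perm]
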