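import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """20 preprocessed segments per class — enough for feature and
    selection tests without long generation times."""
    from ecgwolf.synthetic import SynthConfig, generate_dataset
    cfg = SynthConfig(n_per_class=20, seed=11)
    segments, labels = generate_dataset(cfg)
    return segments, labels


@pytest.fixture(scope="session")
def small_features(small_dataset):
    from ecgwolf.features import FeatureMatrix, extract_all
    segments, _ = small_dataset
    fm = extract_all(segments)
    mu = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0)
    sd[sd == 0] = 1.0
    return FeatureMatrix((fm.values - mu) / sd, fm.feature_names, fm.labels)


@pytest.fixture(scope="session")
def planted_table():
    """Feature table with 5 planted informative + 45 noise columns,
    40 rows per class, and its ground-truth mask."""
    from ecgwolf.synthetic import SynthConfig, generate_feature_table
    return generate_feature_table(SynthConfig(n_per_class=40, seed=21))


@pytest.fixture(scope="session")
def separable_clusters():
    """Five well-separated Gaussian clusters in 8 dimensions,
    100 samples per class: linearly separable classifier fodder."""
    rng = np.random.default_rng(31)
    centers = rng.normal(0.0, 4.0, size=(5, 8))
    X, y = [], []
    for k in range(5):
        X.append(centers[k] + rng.normal(0.0, 0.3, size=(100, 8)))
        y.append(np.full(100, k + 1))
    X = np.concatenate(X)
    y = np.concatenate(y)
    order = rng.permutation(y.size)
    return X[order], y[order]
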