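import numpy as np
import pytest

from cpgc import FeatureTable, SubjectTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_subject(rng):
    """A 9-region white-noise subject at study scale (210 points, TR = 2 s)."""
    return SubjectTimeSeries(data=rng.normal(size=(210, 9)), sampling_interval=2.0)


@pytest.fixture
def planted_table(rng):
    """56 subjects x 30 Gaussian features; features f0..f2 shifted by 1.5 sd
    in the label-1 group."""
    n0, n1, f = 30, 26, 30
    values = rng.normal(size=(n0 + n1, f))
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    values[labels == 1, :3] += 1.5
    return FeatureTable(
        values=values,
        labels=labels,
        feature_names=[f"f{i}" for i in range(f)],
    )


@pytest.fixture
def null_table(rng):
    """Balanced label table with pure-noise features (no class signal)."""
    values = rng.normal(size=(40, 12))
    labels = np.repeat([0, 1], 20)
    return FeatureTable(
        values=values,
        labels=labels,
        feature_names=[f"g{i}" for i in range(12)],
    )
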