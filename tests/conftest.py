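import numpy as np
import pytest

from ggmclust import FitConfig, psychopathology_fixture


@pytest.fixture(scope="session")
def fixture_run():
    """One draw of the 12-variable, 4-cluster synthetic dataset."""
    data, labels, model, communities = psychopathology_fixture(n=1500, seed=1)
    return {"data": data, "labels": labels, "model": model, "communities": communities}


@pytest.fixture(scope="session")
def fast_config():
    """Fit settings used throughout the suite: two seeded k-means restarts
    are ample on well-separated synthetic data and keep runtimes short."""
    return FitConfig(n_restarts=2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
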