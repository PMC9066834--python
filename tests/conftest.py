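import numpy as np
import pytest

from rrbart.simulation import ScenarioConfig, ampute, generate_complete


def random_vip_array(rng, K, M, P):
    """Random VIP_kmp with each (m, p) column on the simplex."""
    v = rng.gamma(1.0, 1.0, size=(K, M, P))
    return v / v.sum(axis=0, keepdims=True)


@pytest.fixture(scope="session")
def small_incomplete():
    """A small amputated dataset shared by imputation/selection tests."""
    data = generate_complete(ScenarioConfig(n=400, n_noise=0, seed=42))
    return data, ampute(data, seed=43)
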