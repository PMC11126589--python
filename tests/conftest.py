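import numpy as np
import pytest
from hypothesis import settings

import squigselect as sq

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return sq.SignalParams.default(seed=0)


@pytest.fixture(scope="session")
def catalog():
    return sq.generate_catalog(10, 1, ("uniform", 300, 900), seed=0)


@pytest.fixture(scope="session")
def small_read_set(catalog, params):
    """100 labeled synthetic reads, half per class."""
    return sq.generate_run_set(catalog, 100, {"target": 0.5, "nontarget": 0.5},
                               n_channels=8, params=params, seed=5)


def scripted_read(adapter_s=1.0, polya_s=1.0, tx_s=5.0, seed=0,
                  adapter_mean=80.0, adapter_mad=25.0,
                  polya_mean=110.0, polya_mad=5.0, tx_mad=30.0,
                  sample_rate=sq.SAMPLE_RATE):
    """Hand-built three-segment signal with exact boundaries (no k-mer
    structure; for trimmer/engine plumbing tests)."""
    rng = np.random.default_rng(seed)
    sigma = 1.0 / 0.674489750196082
    a = adapter_mean + rng.standard_normal(int(adapter_s * sample_rate)) * adapter_mad * sigma
    p = polya_mean + rng.standard_normal(int(polya_s * sample_rate)) * polya_mad * sigma
    t = 95.0 + rng.standard_normal(int(tx_s * sample_rate)) * tx_mad * sigma
    signal = np.concatenate([a, p, t])
    return signal, a.size, a.size + p.size
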