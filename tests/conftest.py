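import numpy as np
import pytest

from hdmea_eap import classify, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def templates_320k():
    return classify.TemplateSet.defaults(320_000.0)


@pytest.fixture(scope="session")
def templates_20k():
    return classify.TemplateSet.defaults(20_000.0)


@pytest.fixture(scope="session")
def small_layout():
    return synthetic.make_layout(12, 6)


def aligned_train(start_s: float, n: int, isi_s: float, sampling_rate: float):
    """Spike train whose times fall exactly on sample ticks."""
    isi = round(isi_s * sampling_rate) / sampling_rate
    t0 = round(start_s * sampling_rate) / sampling_rate
    return t0 + isi * np.arange(n)
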