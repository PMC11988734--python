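import warnings

import numpy as np
import pytest

from afview import SyntheticConfig, synth_record


@pytest.fixture(scope="session")
def paroxysmal_record():
    """120 s two-lead record with one AF episode from 20 s to 60 s."""
    cfg = SyntheticConfig(duration_s=120.0, af_episodes_s=[(20.0, 60.0)], seed=42)
    return synth_record(cfg, record_id="parox")


@pytest.fixture(scope="session")
def sinus_record_clean():
    """60 s noise-free sinus record (for analytic amplitude checks)."""
    cfg = SyntheticConfig(duration_s=60.0, seed=7).noise_free()
    return synth_record(cfg, record_id="sinus_clean")


@pytest.fixture(scope="session")
def af_record_clean():
    """60 s noise-free record entirely inside an AF episode."""
    cfg = SyntheticConfig(duration_s=60.0, af_episodes_s=[(0.0, 60.0)], seed=9).noise_free()
    return synth_record(cfg, record_id="af_clean")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def no_sampler_warnings():
    """Silence the balanced-sampler truncation warning in bulk sampling."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
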