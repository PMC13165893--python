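import logging

import numpy as np
import pytest

import eegoracle as eo

logging.getLogger("eegoracle").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pools():
    """Small exemplar pools shared across tests."""
    rng = np.random.default_rng(42)
    return {
        "eeg": eo.synth_eeg(rng, 60),
        "eog": eo.synth_eog(rng, 40),
        "emg": eo.synth_emg(rng, 40),
    }


@pytest.fixture(scope="session")
def small_benchmark(pools):
    """30-epoch benchmark (10 per kind) for contract checks."""
    rng = np.random.default_rng(7)
    cfg = eo.BenchmarkConfig(n_eog=10, n_emg=10, n_mixed=10)
    return eo.build_benchmark(pools, cfg, rng)


@pytest.fixture(scope="session")
def one_epoch(small_benchmark):
    return small_benchmark[0]
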