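import numpy as np
import pytest

from ripscan import RipSimConfig, fit_contrast, normalize_counts, simulate_ripseq_counts


@pytest.fixture(scope="session")
def recovery_run():
    """One standard planted-enrichment simulation with its fitted contrast."""
    cfg = RipSimConfig(seed=1)
    cm, truth = simulate_ripseq_counts(cfg)
    res = fit_contrast(normalize_counts(cm))
    return cfg, cm, truth, res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
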