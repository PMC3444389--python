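import numpy as np
import pytest

from wavectm import SynthConfig, synthesize_ecg


@pytest.fixture(scope="session")
def default_synth_record():
    """One default synthetic AF record with ground truth (seed 1, theta 0.5)."""
    cfg = SynthConfig(seed=1, variability=0.5)
    record, r_times, clean_fwave = synthesize_ecg(cfg)
    return cfg, record, r_times, clean_fwave


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
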