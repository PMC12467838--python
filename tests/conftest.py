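import copy

import numpy as np
import pytest

from emgfusion import model as M
from emgfusion.benchmark import benchmark_config
from emgfusion.synth import generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def _session_quick_cfg():
    # 500 Hz keeps unit-test feature extraction cheap; the headline
    # benchmark (tests/test_acceptance.py) runs at the 1 kHz default.
    cfg = benchmark_config(7)
    cfg.simulate.fs = 500.0
    cfg.train.max_epochs = 6
    return cfg


@pytest.fixture()
def quick_cfg(_session_quick_cfg):
    return copy.deepcopy(_session_quick_cfg)


@pytest.fixture(scope="session")
def tiny_samples(_session_quick_cfg):
    """Prepared 6-per-class train/test samples, shared across model tests."""
    tr_recs, te_recs = generate_dataset(6, fs=500.0, seed=7)
    tr = M.prepare_samples(tr_recs, _session_quick_cfg)
    te = M.prepare_samples(te_recs, _session_quick_cfg)
    return tr, te
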