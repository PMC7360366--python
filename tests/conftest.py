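import numpy as np
import pytest

import odorstate as od
from odorstate import pipeline as pl


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: fewer cells and the minimum 7+7
    trials, shortened inter-odor intervals."""
    return od.SimConfig(n_cells_per_region=30, n_trials_awake=7,
                        n_trials_kx=7, pre_s=2.5, post_s=2.0)


@pytest.fixture(scope="session")
def pcx_session(small_config):
    bundle, gt = od.generate_session(small_config, "pcx", seed=7)
    return bundle, gt


@pytest.fixture(scope="session")
def pcx_features(pcx_session):
    bundle, _ = pcx_session
    return od.extract_features(bundle)


@pytest.fixture(scope="session")
def pcx_pseudopops(pcx_session, small_config):
    feats = []
    for seed in (7, 8):
        bundle, _ = od.generate_session(small_config, "pcx", seed=seed)
        feats.append(od.extract_features(bundle))
    return pl._pseudopops(feats, "counts_480")
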