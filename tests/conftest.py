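import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from dhrpanel import PanelGenConfig, gen_panel


@pytest.fixture(scope="session")
def small_panel():
    """A small complete panel with iid residuals plus its ground truth."""
    cfg = PanelGenConfig(n_practices=12, n_months=24, seed=42)
    return gen_panel(cfg)


@pytest.fixture(scope="session")
def default_panel():
    """The full 63-practice, 55-month study-shaped panel."""
    cfg = PanelGenConfig(seed=7)
    return gen_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
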