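import numpy as np
import pytest

import valvepet as vp


@pytest.fixture(scope="session")
def ideal_scan():
    """Noise-, blur-, motion- and tilt-free phantom scan: the identity
    pipeline, for exact ground-truth recovery checks."""
    cfg = vp.PhantomConfig.ideal()
    series, truth = vp.generate_phantom(cfg, scan_index=1)
    return cfg, series, truth


@pytest.fixture(scope="session")
def default_scan():
    """One scan at the full default (noisy, blurred, gated) configuration."""
    cfg = vp.PhantomConfig(seed=11)
    series, truth = vp.generate_phantom(cfg, scan_index=1)
    return cfg, series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
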