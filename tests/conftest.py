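import numpy as np
import pytest

from cisscreen.simulate import ScreenSimConfig, simulate_screen


@pytest.fixture(scope="session")
def null_screen():
    """Fully null screen: no planted effects, no noise, no drug."""
    cfg = ScreenSimConfig(
        n_genes=53,
        frac_sensitizers=0.0,
        frac_lethal=0.0,
        count_noise_cv=0.0,
        drug_fa=0.0,
        seed=101,
    )
    return simulate_screen(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
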