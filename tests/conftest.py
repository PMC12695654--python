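import numpy as np
import pytest

from clonetrace.simulate import simulate_donor


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_donor():
    """Two-clone elderly donor with clade-sized clones, fixed seed."""
    return simulate_donor(
        age=76.0,
        n_clones=2,
        pattern_mix=[0.3, 0.2, 0.15, 0.15, 0.1, 0.1],
        seed=5,
        hsc_mcf_range=(0.1, 0.3),
    )
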