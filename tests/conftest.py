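import numpy as np
import pytest

from dynfc.simulate import make_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort with a clear planted effect (K=5, tiny grid)."""
    return make_cohort(n_per_group=(10, 10), n_components=5, T=100,
                       grid_shape=(10, 10, 6), effect_pairs=((0, 1),),
                       delta=0.5, snr=2.0, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
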