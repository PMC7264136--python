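import numpy as np
import pytest

from marquant.phantom import PhantomSpec, StreakSpec, make_pair, render_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The noise-free default phantom stack (arch + insert, no streaks)."""
    return render_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def simulated_pair():
    """One default simulated pair (k_off=10, k_on=4, noise-free, seed 0)."""
    return make_pair(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
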