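import numpy as np
import pytest

from diffbts.schedule import NoiseSchedule, make_schedule, q_sample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def schedule100():
    return make_schedule(100)


@pytest.fixture
def binary_latent(rng):
    """A random 3-channel {-1,+1} label latent on an 8^3 grid."""
    return np.where(rng.random((3, 8, 8, 8)) > 0.7, 1.0, -1.0)


def make_oracle_model(x0_true: np.ndarray, schedule: NoiseSchedule):
    """Denoiser fixture that knows the true clean latent.

    Returns the exact noise consistent with the current latent,
    ``eps = (x_t - sqrt(abar_t) x0) / sqrt(1 - abar_t)``, and the true
    clean latent — the ideal model the sampler equations assume.
    """

    def model(xt, t):
        abar = schedule.alpha_bar(t)
        eps = (xt - np.sqrt(abar) * x0_true) / np.sqrt(1.0 - abar)
        return eps, x0_true.copy()

    return model


@pytest.fixture
def oracle_model(binary_latent, schedule100):
    return make_oracle_model(binary_latent, schedule100)


@pytest.fixture
def noised_latent(binary_latent, schedule100, rng):
    """The latent diffused all the way to t = T."""
    z = rng.standard_normal(binary_latent.shape)
    return q_sample(binary_latent, schedule100.T, z, schedule100)
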