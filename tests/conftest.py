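import numpy as np
import pytest

from mcprofile import ProfilePoints


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def quadratic_points():
    """Noiseless points on 1 - 0.5*(phi - 2)^2 = -1 + 2*phi - 0.5*phi^2."""
    phi = np.linspace(0.0, 4.0, 15)
    ll = 1.0 - 0.5 * (phi - 2.0) ** 2
    return ProfilePoints(phi, ll)


@pytest.fixture
def noisy_concave_points(rng):
    """A concave profile with i.i.d. noise, like a Monte Carlo profile."""
    phi = np.linspace(-1.5, 1.5, 30)
    ll = -0.5 * 4.0 * phi**2 + rng.normal(0.0, 0.8, phi.size)
    return ProfilePoints(phi, ll)


def wls_quadratic_oracle(phi, ll, w):
    """Independent weighted normal-equations solve for a + b*phi + c*phi^2.

    Deliberately naive: builds X'WX explicitly on the raw phi scale and
    inverts it, with no centring or scaling.
    """
    X = np.vander(np.asarray(phi, dtype=float), 3, increasing=True)
    W = np.diag(np.asarray(w, dtype=float))
    A = X.T @ W @ X
    return np.linalg.inv(A) @ X.T @ W @ np.asarray(ll, dtype=float)
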