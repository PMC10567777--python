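import numpy as np
import pytest

from innovurn import NormalizedParams, RawParams
from innovurn.fixtures import worked_example_params


def make_random_normalized(rng: np.random.Generator, n: int) -> NormalizedParams:
    """Random valid float parameters: column-stochastic W, Gamma strictly below W."""
    W = rng.uniform(0.05, 1.0, size=(n, n))
    W /= W.sum(axis=0, keepdims=True)
    Gamma = W * rng.uniform(0.0, 0.9, size=(n, n))
    theta = rng.uniform(0.2, 5.0, size=n)
    return NormalizedParams(theta=theta, Gamma=Gamma, Lambda=W - Gamma)


def make_random_raw(rng: np.random.Generator, n: int, max_balls: int = 6) -> RawParams:
    """Random valid integer ball counts satisfying the balance condition."""
    rho = rng.integers(0, max_balls + 1, size=(n, n))
    np.fill_diagonal(rho, rng.integers(1, max_balls + 1, size=n))
    nu = np.array(
        [[rng.integers(0, rho[j, h] + 1) for h in range(n)] for j in range(n)]
    )
    # keep the diagonal same-color replacement positive
    for h in range(n):
        if nu[h, h] >= rho[h, h]:
            nu[h, h] = rho[h, h] - 1
    N0 = rng.integers(1, 4 * n + 1, size=n)
    return RawParams(N0=N0, rho_hat=rho - nu, nu=nu, rho=rho)


@pytest.fixture(scope="session")
def worked_example() -> NormalizedParams:
    """theta=(1,1), Gamma=[[.2,.1],[.1,.2]], W=[[.7,.3],[.3,.7]] (exact rationals)."""
    return worked_example_params()


@pytest.fixture
def random_normalized():
    return make_random_normalized


@pytest.fixture
def random_raw():
    return make_random_raw
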