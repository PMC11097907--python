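import numpy as np
import pytest
from scipy import linalg

from spontphi.integration import LaggedGaussianModel


def random_lagged_model(rng: np.random.Generator, n: int = 4,
                        radius: float = 0.7) -> LaggedGaussianModel:
    """Analytic lagged Gaussian model of a random stable AR(1) network.

    The stationary covariance solves the discrete Lyapunov equation exactly,
    so no simulation noise enters the property tests that use these models.
    """
    a = rng.normal(scale=0.4, size=(n, n))
    a *= radius * rng.uniform(0.3, 1.0) / max(np.abs(np.linalg.eigvals(a)).max(), 1e-12)
    l = rng.normal(size=(n, n))
    noise = l @ l.T / n + 0.5 * np.eye(n)
    sx = linalg.solve_discrete_lyapunov(a, noise)
    sx = 0.5 * (sx + sx.T)
    return LaggedGaussianModel(cov_x=sx, cov_xy=sx @ a.T, cov_y=sx, tau=1)


def ar_model_from(a: np.ndarray, noise: np.ndarray) -> LaggedGaussianModel:
    sx = linalg.solve_discrete_lyapunov(a, noise)
    sx = 0.5 * (sx + sx.T)
    return LaggedGaussianModel(cov_x=sx, cov_xy=sx @ a.T, cov_y=sx, tau=1)


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream, so outcomes do
    # not depend on which other tests ran before it
    return np.random.default_rng(20240516)
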