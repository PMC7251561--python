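import numpy as np
import pytest
from scipy.integrate import quad

from fracprey import ModelParams


@pytest.fixture
def params() -> ModelParams:
    """Baseline parameter table used throughout."""
    return ModelParams()


def weight_integrals_quad(n: int, ell: int, alpha: float, dt: float = 1.0):
    """Adaptive-quadrature oracle for the Adams-Bashforth panel integrals.

    Computes ``int_{t_l}^{t_{l+1}} (t - t_{l-1}) (t_{n+1} - t)^(alpha-1) dt``
    and the same with ``(t - t_l)``, handling the ``ell == n`` case (kernel
    singular at the right endpoint) with a weighted quadrature rule.
    Independent of the closed-form weight implementation.
    """
    tl, tl1, tlm1 = ell * dt, (ell + 1) * dt, (ell - 1) * dt
    tn1 = (n + 1) * dt
    if ell == n:
        ia, _ = quad(lambda t: t - tlm1, tl, tl1, weight="alg", wvar=(0.0, alpha - 1.0))
        ib, _ = quad(lambda t: t - tl, tl, tl1, weight="alg", wvar=(0.0, alpha - 1.0))
    else:
        ia, _ = quad(lambda t: (t - tlm1) * (tn1 - t) ** (alpha - 1.0), tl, tl1)
        ib, _ = quad(lambda t: (t - tl) * (tn1 - t) ** (alpha - 1.0), tl, tl1)
    return ia, ib


def uniform_grid(T: float, N: int) -> np.ndarray:
    return np.linspace(0.0, T, N + 1)
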