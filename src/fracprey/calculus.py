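"""Numerical ABC fractional calculus on uniform grids.

Implements the left-sided Atangana-Baleanu (AB) fractional integral, the
ABC fractional derivative, the inversion formula that turns
``ABC-D^alpha sigma = omega`` into a Volterra equation, and the closed-form
solution of the scalar linear test equation ``ABC-D^alpha y = lam * y``.
The linear closed form is the analytic oracle against which the time
steppers in :mod:`fracprey.solver` are validated.

All operators act on functions sampled on a uniform grid ``t_l = l * dt``.
The weakly singular Riemann-Liouville integral inside the AB integral is
evaluated by product integration: the integrand is replaced by its
piecewise-linear interpolant and integrated exactly against the kernel
``(t - theta)^(alpha-1)``, which keeps the quadrature error ``O(dt^2)``
for twice-differentiable integrands instead of the ``O(dt^alpha)`` a naive
trapezoid on the singular kernel would give.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .special import FractionalOrder, mittag_leffler

__all__ = [
    "SampledFunction",
    "LinearTestProblem",
    "ab_integral",
    "abc_derivative",
    "lemma1_solution",
    "linear_abc_exact",
    "rl_integral_weights",
]

_GRID_RTOL = 1e-12


@dataclass(frozen=True)
class SampledFunction:
    """A real function sampled on a uniform grid starting at zero."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("grid must be one-dimensional with at least 2 points")
        if values.shape != grid.shape:
            raise ValueError("values and grid must have equal length")
        if grid[0] != 0.0:
            raise ValueError("grid must start at 0")
        steps = np.diff(grid)
        dt = steps[0]
        if dt <= 0 or not np.allclose(steps, dt, rtol=_GRID_RTOL, atol=0.0):
            raise ValueError("grid spacing must be positive and uniform")

    @property
    def dt(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def horizon(self) -> float:
        return float(self.grid[-1])

    @classmethod
    def from_callable(cls, func, T: float, N: int) -> "SampledFunction":
        grid = np.linspace(0.0, T, N + 1)
        return cls(grid, np.asarray([func(t) for t in grid], dtype=float))


def rl_integral_weights(n_points: int, alpha: float) -> np.ndarray:
    """Product-trapezoid weights for the Riemann-Liouville integral.

    Returns a lower-triangular matrix ``w`` such that, for a function given
    by samples ``f_j`` on a uniform grid with spacing ``dt``,

    ``int_0^{t_n} (t_n - theta)^(alpha-1) f(theta) dtheta
      ~= dt^alpha / (alpha (alpha+1)) * sum_j w[n, j] f_j``

    where ``f`` is interpolated linearly between grid nodes and the kernel
    moments are integrated exactly.  The weights depend on ``n - j`` except
    at the two ends:

    * ``w[n, 0] = (n-1)^(alpha+1) - n^alpha (n - alpha - 1)``
    * ``w[n, j] = (n-j+1)^(alpha+1) - 2 (n-j)^(alpha+1) + (n-j-1)^(alpha+1)``
      for ``0 < j < n``
    * ``w[n, n] = 1``

    At ``alpha = 1`` these reduce to the ordinary trapezoid rule.
    """
    if n_points < 1:
        raise ValueError("need at least one grid point")
    j = np.arange(n_points, dtype=float)
    # interior weights are the second difference of m^(alpha+1) in the lag m
    w = np.zeros((n_points, n_points))
    for n in range(1, n_points):
        w[n, n] = 1.0
        w[n, 0] = (n - 1.0) ** (alpha + 1.0) - n**alpha * (n - alpha - 1.0)
        if n > 1:
            m = n - j[1:n]  # n-j for j = 1 .. n-1
            w[n, 1:n] = (m + 1.0) ** (alpha + 1.0) - 2.0 * m ** (alpha + 1.0) + (
                m - 1.0
            ) ** (alpha + 1.0)
    return w


def _rl_integral(values: np.ndarray, dt: float, alpha: float) -> np.ndarray:
    n = values.shape[0]
    w = rl_integral_weights(n, alpha)
    scale = dt**alpha / (alpha * (alpha + 1.0))
    return scale * (w @ values)


def ab_integral(f: SampledFunction, order: FractionalOrder) -> SampledFunction:
    """Left-sided AB fractional integral of ``f`` on its own grid.

    ``AB-I^alpha f(t) = (1-alpha)/ABC[alpha] * f(t)
    + alpha / (ABC[alpha] Gamma(alpha)) * int_0^t (t-theta)^(alpha-1) f dtheta``.

    At ``alpha = 1`` the local term vanishes and the operator degenerates to
    the plain cumulative integral (evaluated by the trapezoid rule).
    """
    alpha = order.alpha
    b = order.abc_norm
    rl = _rl_integral(f.values, f.dt, alpha)
    values = (1.0 - alpha) / b * f.values + alpha / (b * math.gamma(alpha)) * rl
    return SampledFunction(f.grid, values)


def _finite_difference(values: np.ndarray, dt: float) -> np.ndarray:
    """Second-order central differences, first-order one-sided at the ends."""
    d = np.empty_like(values)
    d[1:-1] = (values[2:] - values[:-2]) / (2.0 * dt)
    d[0] = (values[1] - values[0]) / dt
    d[-1] = (values[-1] - values[-2]) / dt
    return d


def abc_derivative(f: SampledFunction, order: FractionalOrder) -> SampledFunction:
    """Left-sided ABC fractional derivative of ``f`` on its own grid.

    ``ABC-D^alpha f(t) = ABC[alpha]/(1-alpha)
    * int_0^t E_alpha(-alpha/(1-alpha) (t-theta)^alpha) f'(theta) dtheta``.

    The Mittag-Leffler kernel decays from 1 and is nonsingular, so the
    integral is evaluated by the trapezoid rule on the pointwise product of
    kernel and difference-quotient samples; the kernel depends on
    ``t - theta`` only and is therefore computed once per lag.  This
    operator exists as a verification utility (the solvers work with the
    integral form); its accuracy is O(dt) at the grid ends where the
    one-sided difference quotient is first order.

    Raises
    ------
    ValueError
        If ``alpha = 1``: the kernel constant ``alpha/(1-alpha)`` diverges
        and the classical derivative should be used instead.
    """
    alpha = order.alpha
    if alpha >= 1.0:
        raise ValueError(
            "abc_derivative requires alpha < 1; at alpha = 1 use the "
            "classical derivative"
        )
    rate = alpha / (1.0 - alpha)
    dt = f.dt
    n = f.values.shape[0]
    kernel = np.asarray(
        [mittag_leffler(alpha, -rate * (j * dt) ** alpha) for j in range(n)]
    )
    fp = _finite_difference(f.values, dt)
    out = np.zeros(n)
    for i in range(1, n):
        integrand = kernel[i::-1] * fp[: i + 1]
        out[i] = np.trapezoid(integrand, dx=dt)
    return SampledFunction(f.grid, order.abc_norm / (1.0 - alpha) * out)


def lemma1_solution(
    omega: SampledFunction, sigma0: float, order: FractionalOrder
) -> SampledFunction:
    """Solution of ``ABC-D^alpha sigma = omega`` with ``sigma(0) = sigma0``.

    The inversion formula is ``sigma = sigma0 + AB-I^alpha omega``.  Note
    that unless ``omega(0) = 0`` the right-hand side does not equal
    ``sigma0`` at ``t = 0``: the local term of the AB integral introduces a
    jump ``(1-alpha)/ABC[alpha] * omega(0)`` at the origin.  This is a
    structural feature of the ABC operator, not a bug.
    """
    integ = ab_integral(omega, order)
    return SampledFunction(omega.grid, sigma0 + integ.values)


@dataclass(frozen=True)
class LinearTestProblem:
    """The scalar linear test equation ``ABC-D^alpha y = lam * y``.

    Its exact solution is a scaled Mittag-Leffler function (see
    :func:`linear_abc_exact`); the problem serves as the analytic oracle
    for the time steppers.  The closed form requires
    ``ABC[alpha] - lam (1 - alpha) != 0``; the constructor rejects the
    degenerate rate.
    """

    lam: float
    y0: float
    order: FractionalOrder
    _denom: float = field(init=False)

    def __post_init__(self) -> None:
        alpha = self.order.alpha
        denom = 1.0 - self.lam * (1.0 - alpha) / self.order.abc_norm
        if abs(denom) < 1e-14:
            raise ValueError(
                "degenerate linear problem: lam equals "
                "ABC[alpha] / (1 - alpha); the resolvent does not exist"
            )
        object.__setattr__(self, "_denom", denom)

    def rhs(self, t: float, y):
        return self.lam * np.asarray(y)


def linear_abc_exact(problem: LinearTestProblem, t) -> np.ndarray | float:
    """Exact solution of the linear ABC test equation at time(s) ``t``.

    Solving the Laplace-transform relation of the ABC derivative for
    ``Y(s)`` gives ``Y = y0 (B/(B - lam(1-alpha))) s^(alpha-1) /
    (s^alpha - lam alpha/(B - lam(1-alpha)))`` with ``B = ABC[alpha]``,
    whose inverse is

    ``y(t) = y0 / D * E_alpha( (lam alpha / B) / D * t^alpha )``,
    ``D = 1 - lam (1 - alpha) / B``.

    For ``alpha < 1`` and ``lam != 0`` the solution jumps at the origin:
    ``y(0+) = y0 / D != y0``.  This function returns the ``t > 0`` branch
    value also at ``t = 0``, i.e. ``y0 / D``; the initial condition proper
    lives only in the Volterra formulation.
    """
    alpha = problem.order.alpha
    b = problem.order.abc_norm
    d = problem._denom
    coeff = (problem.lam * alpha / b) / d
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("time must be nonnegative")
    flat = np.atleast_1d(tt)
    out = np.asarray(
        [problem.y0 / d * mittag_leffler(alpha, coeff * ti**alpha) for ti in flat]
    )
    return float(out[0]) if tt.ndim == 0 else out.reshape(tt.shape)
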