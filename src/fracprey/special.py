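"""One-parameter Mittag-Leffler function and the ABC normalization.

These two scalars underlie everything else in the package: the
Mittag-Leffler function :math:`E_\\alpha(z) = \\sum_k z^k/\\Gamma(\\alpha k+1)`
is the nonsingular kernel of the Atangana-Baleanu-Caputo (ABC) derivative,
and the normalization function ``ABC[alpha]`` scales the operator so that it
reduces to the classical derivative at ``alpha = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.special import gammaln

__all__ = [
    "FractionalOrder",
    "mittag_leffler",
    "normalization",
    "ConvergenceError",
]

#: hard cap on the number of series terms before declaring failure
_MAX_TERMS = 10_000

#: ratio of largest intermediate term to final sum above which the fixed
#: precision result is considered destroyed by cancellation
_CANCEL_GUARD = 1e8

_DEFAULT_TOL = 1e-12


class ConvergenceError(RuntimeError):
    """Raised when the Mittag-Leffler series fails to converge."""


def normalization(alpha: float, convention: str = "linear") -> float:
    """Normalization function ``ABC[alpha]`` of the ABC operator.

    Parameters
    ----------
    alpha
        Fractional order, must lie in ``(0, 1]``.
    convention
        ``"linear"`` (default) uses ``alpha / (2 - alpha)``;
        ``"ab"`` uses the alternative ``1 - alpha + alpha/Gamma(alpha)``
        found elsewhere in the fractional-calculus literature.  The switch
        exists for sensitivity checks only; every default in this package
        uses the linear convention.

    Returns
    -------
    float
        ``ABC[alpha] > 0``; equals 1 exactly at ``alpha = 1`` in both
        conventions.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"fractional order must be in (0, 1], got {alpha!r}")
    if convention == "linear":
        return alpha / (2.0 - alpha)
    if convention == "ab":
        return 1.0 - alpha + alpha / math.gamma(alpha)
    raise ValueError(f"unknown normalization convention {convention!r}")


@dataclass(frozen=True)
class FractionalOrder:
    """A fractional order ``alpha`` with its derived normalization.

    The order parameterizes every operator in the package.  Only
    ``alpha`` in ``(0, 1]`` is accepted: the normalization formula
    ``alpha/(2 - alpha)`` vanishes at 0, so the operators are not
    well-scaled there and the endpoint is excluded outright.
    """

    alpha: float
    convention: str = "linear"
    abc_norm: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "abc_norm", normalization(self.alpha, self.convention)
        )

    @property
    def is_classical(self) -> bool:
        """True when the order degenerates to the ordinary derivative."""
        return self.alpha == 1.0


def _series_float(alpha: float, z: float, tol: float) -> tuple[float, float, int]:
    """Fixed-precision evaluation of the defining series.

    Returns ``(sum, largest_term_magnitude, n_terms)``.  Terms are formed
    from logarithms, ``|t_k| = exp(k log|z| - lgamma(alpha k + 1))``, so a
    huge intermediate term cannot overflow before the cancellation guard
    has a chance to look at it.
    """
    total = 1.0  # k = 0 term: z^0 / Gamma(1)
    largest = 1.0
    if z == 0.0:
        return total, largest, 1
    log_absz = math.log(abs(z))
    sign_z = 1.0 if z > 0 else -1.0
    sign = 1.0
    for k in range(1, _MAX_TERMS + 1):
        sign *= sign_z
        log_term = k * log_absz - gammaln(alpha * k + 1.0)
        if log_term > 700.0:  # term would overflow a double; keep scanning
            largest = math.inf
            continue
        term = sign * math.exp(log_term)
        total += term
        largest = max(largest, abs(term))
        if abs(term) < tol * max(1.0, abs(total)) and log_term < 0.0:
            return total, largest, k + 1
    raise ConvergenceError(
        f"Mittag-Leffler series did not converge within {_MAX_TERMS} terms "
        f"for alpha={alpha}, z={z}"
    )


def _series_mpmath(alpha: float, z: float, tol: float, lost_digits: float) -> float:
    """Arbitrary-precision re-evaluation used when cancellation is detected."""
    import mpmath as mp

    dps = int(lost_digits) + 25
    with mp.workdps(dps):
        a = mp.mpf(alpha)
        zz = mp.mpf(z)
        total = mp.mpf(1)
        term_tol = mp.mpf(tol)
        for k in range(1, _MAX_TERMS + 1):
            term = zz**k / mp.gamma(a * k + 1)
            total += term
            if abs(term) < term_tol * max(1, abs(total)) and abs(term) < 1:
                return float(total)
    raise ConvergenceError(
        f"Mittag-Leffler series did not converge in arbitrary precision "
        f"for alpha={alpha}, z={z}"
    )


def mittag_leffler(alpha: float, z: float, tol: float = _DEFAULT_TOL) -> float:
    """Evaluate the one-parameter Mittag-Leffler function ``E_alpha(z)``.

    The series :math:`\\sum_{k\\ge 0} z^k/\\Gamma(\\alpha k+1)` is summed in
    double precision until the current term drops below ``tol`` times the
    running sum.  For negative arguments the series alternates and the
    partial sums can cancel catastrophically; when the largest intermediate
    term exceeds ``1e8`` times the final sum, the value is recomputed with
    ``mpmath`` at a working precision chosen from the number of digits lost.

    Parameters
    ----------
    alpha
        Series parameter, any positive real (not restricted to (0, 1]).
    z
        Real argument.  The supported range is ``|z| <= 50``; far outside
        it the series may exhaust the term cap for small ``alpha``.
    tol
        Relative truncation tolerance (default ``1e-12``).

    Returns
    -------
    float
        ``E_alpha(z)``, with absolute error on the order of ``10 * tol``
        on the supported range.
    """
    if alpha <= 0:
        raise ValueError(f"Mittag-Leffler parameter must be positive, got {alpha!r}")
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol!r}")
    if z == 0.0:
        return 1.0
    if alpha == 1.0:
        return math.exp(z)
    total, largest, _ = _series_float(alpha, z, tol)
    if largest > _CANCEL_GUARD * max(1.0, abs(total)):
        # the float sum is untrustworthy, so size the working precision by
        # the largest term alone (the true sum may be arbitrarily smaller)
        if math.isinf(largest):
            # individual terms overflowed double precision entirely
            lost = 320.0 + abs(z) ** (1.0 / alpha) / math.log(10.0)
        else:
            lost = math.log10(largest)
        return _series_mpmath(alpha, z, tol, lost)
    return total
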