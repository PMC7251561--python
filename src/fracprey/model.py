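"""Three-species eco-epidemiological prey-predator model.

The state is ``(P, S, I)``: prey density, susceptible-predator density and
infected-predator density.  Prey grow logistically with carrying capacity
``k`` and are consumed through a Holling-type saturating response
``b P S / (a + P)``; the predator population is split into susceptible and
infected compartments coupled by a mass-action transmission term with
coefficient ``d``.  The model is posed with an ABC fractional derivative of
order ``alpha`` acting on each species, so trajectories carry a
power-law memory of their history.

Alongside the vector field this module provides the Volterra-form residual
(the defect of a trajectory in the equivalent fractional integral
equation) and the existence / Ulam-Hyers stability diagnostics: Lipschitz
constants ``L1..L3`` of the three kernels under assumed sup-norm bounds,
the contraction factors ``Lambda1..Lambda3`` whose smallness guarantees a
unique solution, and the stability constants ``kappa`` and
``lambda1..lambda3`` that bound how far an approximate trajectory can sit
from the exact one.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from .calculus import SampledFunction, ab_integral
from .special import FractionalOrder

__all__ = [
    "ModelParams",
    "StateVector",
    "DiagnosticsReport",
    "SupNormBounds",
    "rhs",
    "rhs_jacobian",
    "integral_residual",
    "diagnostics",
]


@dataclass(frozen=True)
class ModelParams:
    """The twelve ecological constants of the simulation scenario.

    Defaults are the baseline parameter table: note that the prey start at
    ``P0 = 0.5``, more than one hundred times the carrying capacity
    ``k = 0.003``, so the prey compartment is in strong logistic decline
    from the outset.
    """

    a: float = 0.00073  #: saturation constant of the Holling response
    b: float = 0.0001  #: search rate of prey by susceptible predators
    c: float = 0.0003  #: prey-to-predator conversion rate
    d: float = 0.007  #: disease transmission coefficient
    k: float = 0.003  #: prey carrying capacity
    b1: float = 0.004  #: proportionality constant of prey growth
    r1: float = 0.0003  #: prey loss rate to infected predators
    m: float = 0.004  #: susceptible-predator death rate
    n: float = 0.003  #: infected-predator death rate
    P0: float = 0.5  #: initial prey density
    S0: float = 0.3  #: initial susceptible-predator density
    I0: float = 0.2  #: initial infected-predator density

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0")
        if self.a <= 0 or self.k <= 0:
            raise ValueError("a and k appear in denominators and must be positive")

    @property
    def initial_state(self) -> np.ndarray:
        return np.array([self.P0, self.S0, self.I0])

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "ModelParams":
        """Build parameters from a JSON file/string/dict.

        Missing keys fall back to the defaults; unknown keys are rejected.
        """
        if isinstance(source, dict):
            data = source
        else:
            path = Path(source)
            text = path.read_text() if path.exists() else str(source)
            data = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass(frozen=True)
class StateVector:
    """Species densities ``(P, S, I)`` at one instant."""

    P: float
    S: float
    I: float

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.S, self.I])

    @classmethod
    def from_array(cls, arr) -> "StateVector":
        p, s, i = np.asarray(arr, dtype=float)
        return cls(float(p), float(s), float(i))


def rhs(t: float, state, params: ModelParams) -> np.ndarray:
    """The three kernels ``(W1, W2, W3)`` of the model, as printed.

    ``W1 = b1 P (1 - P/k) - b P S/(a + P) - r1 P I``
    ``W2 = c b P S/(a + P) - d S I - m S^2``
    ``W3 = -n I + d I + c k I P``

    The system is autonomous; ``t`` is accepted for solver compatibility
    and ignored.  ``W3`` is implemented exactly as written, including the
    ``+ d I`` growth term for the infected compartment.
    """
    arr = state.as_array() if isinstance(state, StateVector) else np.asarray(
        state, dtype=float
    )
    p, s, i = arr
    if p == -params.a:
        raise ZeroDivisionError(
            f"Holling denominator vanishes at state P={p} (pole at -a)"
        )
    holling = params.b * p * s / (params.a + p)
    w1 = params.b1 * p * (1.0 - p / params.k) - holling - params.r1 * p * i
    w2 = params.c * holling - params.d * s * i - params.m * s * s
    w3 = -params.n * i + params.d * i + params.c * params.k * i * p
    return np.array([w1, w2, w3])


def rhs_jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with respect to the state."""
    p, s, i = np.asarray(state, dtype=float)
    a, b, c, d, k = params.a, params.b, params.c, params.d, params.k
    denom = a + p
    dholl_dp = b * s * a / denom**2
    jac = np.array(
        [
            [
                params.b1 * (1.0 - 2.0 * p / k) - dholl_dp - params.r1 * i,
                -b * p / denom,
                -params.r1 * p,
            ],
            [
                c * dholl_dp,
                c * b * p / denom - d * i - 2.0 * params.m * s,
                -d * s,
            ],
            [c * k * i, 0.0, -params.n + d + c * k * p],
        ]
    )
    return jac


def integral_residual(
    grid: np.ndarray,
    states: np.ndarray,
    params: ModelParams,
    order: FractionalOrder,
) -> np.ndarray:
    """Per-species maximum defect of a trajectory in the Volterra form.

    For each species ``X`` with kernel ``W_X`` the residual at a grid point
    ``t`` is ``|X(t) - X(0) - AB-I^alpha[W_X(., state(.))](t)|``; the
    maximum over the grid is returned as an array ``(res_P, res_S, res_I)``.

    A trajectory of the fractional model should drive this defect to zero
    under grid refinement **away from the origin**.  At ``t = 0`` itself the
    residual equals ``(1-alpha)/ABC[alpha] * |W_X(0, state0)|``, which is a
    property of the model (the AB integral's local term does not vanish at
    0 unless the kernels do) and is independent of the solver and the grid.
    """
    grid = np.asarray(grid, dtype=float)
    states = np.asarray(states, dtype=float)
    if states.shape[0] != grid.shape[0]:
        raise ValueError("states and grid lengths differ")
    w = np.asarray([rhs(t, y, params) for t, y in zip(grid, states)])
    res = np.empty(3)
    for j in range(3):
        integ = ab_integral(SampledFunction(grid, w[:, j]), order)
        defect = states[:, j] - states[0, j] - integ.values
        res[j] = np.max(np.abs(defect))
    return res


@dataclass(frozen=True)
class SupNormBounds:
    """Assumed sup-norm bounds entering the Lipschitz constants.

    ``A1`` and ``A1star`` bound the prey components of the two trajectories
    being compared, ``C1``/``C1star`` the susceptible predators, ``D1`` the
    infected predators.
    """

    A1: float
    A1star: float
    C1: float
    C1star: float
    D1: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"bound {f.name} must be positive")

    @classmethod
    def default_for(cls, params: ModelParams) -> "SupNormBounds":
        """``max(1, initial density)`` per species, used when no bounds are given."""
        p = max(1.0, params.P0)
        s = max(1.0, params.S0)
        i = max(1.0, params.I0)
        return cls(A1=p, A1star=p, C1=s, C1star=s, D1=i)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Existence and Ulam-Hyers stability constants of the model.

    ``Lambda_l < 1`` for all three kernels is the contraction condition
    under which the solution exists, is unique, and is Ulam-Hyers stable
    with constants ``lambda_l = 2 kappa / (1 - Lambda_l)``.  When a
    ``Lambda_l >= 1`` the corresponding ``lambda_l`` is undefined and
    reported as ``None``.
    """

    alpha: float
    T: float
    bounds: SupNormBounds
    L1: float
    L2: float
    L3: float
    Lambda1: float
    Lambda2: float
    Lambda3: float
    kappa: float
    lambda1: float | None
    lambda2: float | None
    lambda3: float | None
    contraction_ok: bool

    def to_json(self, path: str | Path | None = None) -> str:
        data = asdict(self)
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def diagnostics(
    params: ModelParams,
    order: FractionalOrder,
    T: float,
    bounds: SupNormBounds | None = None,
    lipschitz_override: tuple[float, float, float] | None = None,
) -> DiagnosticsReport:
    """Compute the existence / stability diagnostic constants.

    The Lipschitz constants use the printed formulas

    ``L1 = b1 + (b1/k)(A1 + A1*) + a b C1 + r1 D1``
    ``L2 = (c b / (a + A1)) A1 + d D1 + m (C1 + C1*)``
    ``L3 = n + d + c k A1``

    and are reproduced as defined constants of the analysis, not asserted
    to be sharp bounds of the actual kernels.  ``lipschitz_override``
    replaces all three ``L`` values (useful for what-if checks).

    Contraction factors, perturbation constant and stability constants:

    ``Lambda_l = [(1-alpha)/ABC[alpha] + T^alpha/(ABC[alpha] Gamma(alpha))] L_l``
    ``kappa    = (Gamma(alpha) - Gamma(alpha+1) + T^alpha) / (ABC[alpha] Gamma(alpha))``
    ``lambda_l = 2 kappa / (1 - Lambda_l)``  (only when ``Lambda_l < 1``)
    """
    if T <= 0:
        raise ValueError("horizon T must be positive")
    if bounds is None:
        bounds = SupNormBounds.default_for(params)
    alpha = order.alpha
    b_norm = order.abc_norm
    if lipschitz_override is not None:
        L1, L2, L3 = (float(v) for v in lipschitz_override)
    else:
        L1 = (
            params.b1
            + params.b1 / params.k * (bounds.A1 + bounds.A1star)
            + params.a * params.b * bounds.C1
            + params.r1 * bounds.D1
        )
        L2 = (
            params.c * params.b / (params.a + bounds.A1) * bounds.A1
            + params.d * bounds.D1
            + params.m * (bounds.C1 + bounds.C1star)
        )
        L3 = params.n + params.d + params.c * params.k * bounds.A1
    gam = math.gamma(alpha)
    factor = (1.0 - alpha) / b_norm + T**alpha / (b_norm * gam)
    lambdas_big = tuple(factor * L for L in (L1, L2, L3))
    kappa = (gam - math.gamma(alpha + 1.0) + T**alpha) / (b_norm * gam)
    uh = tuple(
        (2.0 * kappa / (1.0 - lam)) if lam < 1.0 else None for lam in lambdas_big
    )
    return DiagnosticsReport(
        alpha=alpha,
        T=T,
        bounds=bounds,
        L1=L1,
        L2=L2,
        L3=L3,
        Lambda1=lambdas_big[0],
        Lambda2=lambdas_big[1],
        Lambda3=lambdas_big[2],
        kappa=kappa,
        lambda1=uh[0],
        lambda2=uh[1],
        lambda3=uh[2],
        contraction_ok=max(lambdas_big) < 1.0,
    )
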