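# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. Everything quantitative stated here is
computed by the tests or the example scripts; nothing is asserted from
memory.

## The operator and its normalization

The ABC derivative of order `α ∈ (0, 1]` convolves the ordinary derivative
with the nonsingular kernel `E_α(−α/(1−α)(t−θ)^α)` and scales it by
`ABC[α]/(1−α)`. We take `ABC[α] = α/(2−α)` (so `ABC[1] = 1` exactly) and
exclude `α = 0` from the domain: the linear normalization vanishes there,
and the operator family is used only on `(0, 1]`. An alternative
convention `B(α) = 1−α+α/Γ(α)`, common elsewhere in the fractional
literature, is available behind `normalization(..., convention="ab")` for
sensitivity checks; every default uses the linear form. At `α = 1` the AB
integral degenerates to the plain integral and the derivative to the
classical one (the derivative routine refuses `α = 1` rather than taking
the singular limit `α/(1−α) → ∞`).

The kernel argument is taken with the standard decaying sign,
`E_α(−α/(1−α)(t−θ)^α)`; a growing kernel would make the operator
ill-posed as a derivative of fractional type.

## Mittag-Leffler evaluation

`E_α(z)` is summed termwise with terms formed in log-space
(`exp(k log|z| − lgamma(αk+1))`), stopping when the current term falls
below `tol · max(1, |partial sum|)` (default `tol = 1e−12`), with a hard
cap of 10 000 terms. On the negative axis the series alternates with
intermediate terms up to `~exp(|z|^{1/α})`, destroying double precision;
when the largest intermediate term exceeds `1e8 ×` the final sum, the
value is recomputed with mpmath at a working precision sized by the
largest term's magnitude (not by the — untrustworthy — float sum). The
practical range is `|z| ≲ 50` for moderate `α`; small `α` with large `|z|`
can exhaust the term cap, which raises a convergence error rather than
returning a wrong number.

## Grid operators

Functions live on uniform grids `t_ℓ = ℓΔ`. The weakly singular integral
`∫₀^{t_n} (t_n−θ)^{α−1} f(θ) dθ` is evaluated by product integration: `f`
is replaced by its piecewise-linear interpolant and the kernel moments are
integrated exactly, giving the classical product-trapezoid weights
(second differences of `m^{α+1}` in the lag, with closed-form end
corrections). At `α = 1` this reduces to the trapezoid rule to machine
precision. For twice-differentiable integrands the error is `O(Δ²)`; for
integrands with a `t^α` cusp at the origin (every ABC solution with
incompatible data has one) the observed rate drops to `O(Δ^{1+α})`.

The ABC derivative routine is a verification utility: difference
quotients (central inside, one-sided first-order at the ends) are
integrated against the pointwise Mittag-Leffler kernel — nonsingular, so
the trapezoid rule suffices. Its round-trip with the AB integral
(`AB-I^α ∘ ABC-D^α f = f − f(0)`) converges at rate ≈ 1.5 on smooth
functions (measured in the tests).

## The linear oracle

For `ABC-D^α y = λy`, `y(0) = y₀`, solving the operator's Laplace-transform
relation gives

```
y(t) = y₀/D · E_α( (λα/B)/D · t^α ),   D = 1 − λ(1−α)/B,   B = ABC[α],
```

valid when `D ≠ 0` (the constructor rejects the degenerate rate). The
formula was re-derived and checked against Talbot numerical inversion of
the transform (agreement ≈ 3e−14) and against adaptive-quadrature
residuals in the Volterra form (≈ 1e−11); frozen values of both checks are
asserted in the tests.

Note `y(0⁺) = y₀/D ≠ y₀` whenever `α < 1` and `λ ≠ 0`: the Volterra form
`y = y₀ + (1−α)/B·λy + RL-term` forces a jump at the origin unless the
right-hand side vanishes at `t = 0`. This is a structural property of the
ABC operator with incompatible initial data and recurs throughout the
package (see below).

## The Adams–Bashforth scheme

On each panel `[t_ℓ, t_{ℓ+1}]` the right-hand side is replaced by the
line through its values at `t_{ℓ−1}` and `t_ℓ` and integrated exactly
against `(t_{n+1}−t)^{α−1}`, giving the closed-form bracket factors

```
A = (n+1−ℓ)^α(n−ℓ+2+α) − (n−ℓ)^α(n−ℓ+2+2α)
B = (n+1−ℓ)^{α+1} − (n−ℓ)^α(n−ℓ+1+α)
```

(with `0^α := 0`), assembled as

```
y_{n+1} = y₀ + (1−α)/ABC[α] · W(t_n, y_n)
        + α Δ^α/(ABC[α] Γ(α+2)) · Σ_ℓ [A W_ℓ − B W_{ℓ−1}] .
```

Choices that the construction leaves open:

- **First-step history.** The `ℓ = 0` term references `W(t_{−1}, y_{−1})`,
  which is undefined; we bootstrap `W(t_{−1}) := W(t_0, y_0)` (constant
  history, equivalent to a product-Euler first panel). This preserves the
  startup consistency order with minimal assumptions.
- **Full history.** The `O(N²)` sum is evaluated exactly; no short-memory
  truncation. At desk scale (`N ≤ 5000`) fidelity beats speed.
- **Weights depend only on the lag** `n−ℓ`, so they are precomputed once
  per run as vectors and each step is a dot product.

At `α = 1` every bracket is `(A, B) = (3, 1)` and the scheme is exactly
classical two-step Adams–Bashforth (measured order ≈ 2); at fractional
orders the measured order on the linear oracle is ≈ 1.

### Stability of the explicit local term

The local part `(1−α)/ABC[α] · W(t_n, y_n)` is evaluated at the lagged
state, so each step performs one fixed-point sweep of the implicit local
balance. Perturbations are amplified per step by roughly
`(1−α)/ABC[α] · ∂W/∂y = (1−α)(2−α)/α · ∂W/∂y`, **independent of Δ**. When
this factor exceeds one in magnitude the scheme cannot converge:

- Linear fixture `λ = −1`: the factor is 2.4 at `α = 0.4` — measured
  divergence `~2.4ⁿ`, overflow within 800 steps; at `α = 0.7` the factor
  is 0.56 and the scheme converges with order ≈ 1.
- Default three-species scenario: `∂W₁/∂P ≈ b₁(1 − 2P₀/k) ≈ −1.33`
  (the prey start at 167× carrying capacity), so the factor is ≈ 3.2 at
  `α = 0.4` (blow-up at step 18 of the default grid), ≈ 1.24 at `α = 0.6`
  (bounded startup oscillation that damps as prey decline), ≈ 0.4 at
  `α = 0.8` (damped oscillation over a few steps), 0 at `α = 1`.

The solver detects non-finite states and aborts with the step index; the
scenario runner records the failure per order and continues. No
step-size reduction can fix this — an implicit local solve could, but
that would be a different scheme than the one implemented.

## Picard iteration

The Volterra form is iterated globally on the grid,
`y^{(m)} = y₀ + (1−α)/B · W(·, y^{(m−1)}) + RL-product-integral`, starting
from the constant `y₀`. Successive sup-norm differences decay
geometrically with ratio bounded by the contraction factor `Λ` of the
existence analysis (measured ratios ≤ 0.59 vs `Λ = 0.79` on the linear
fixture at `α = 0.8`, `λ = −0.5`, `T = 1`); three consecutive growing
differences raise a contraction-failure error pointing at the `Λ` check.
The grid value at `t = 0` is pinned to the initial condition — the
fixed point of the iteration formula at `t = 0` is the jumped value
`y₀ + (1−α)/B·W(0, y₀)`, and pinning keeps the trajectory contract
(`states[0]` is the supplied initial condition) uniform across solvers.

## Incompatible initial data and what the residual can show

With the default parameter table, `W₁(0, y₀) = −0.331 ≠ 0`, so the
Volterra solution jumps at `t = 0⁺` (by `≈ −0.10` in prey density at
`α = 0.8`). Consequences, all measured:

- The Volterra residual at the origin equals `(1−α)/ABC[α]·|W₁(0)|`
  (= 0.0994 at `α = 0.8`) for *any* trajectory whose first sample is the
  prescribed initial condition — it does not shrink with the grid and is
  a property of the model, not of the solver. Away from the origin the
  residual is `O(Δ)` (8e−4 at `Δ = 0.05`), dominated by the scheme's
  lagged local term.
- Adams–Bashforth relaxes onto the jumped branch over a few steps while
  Picard lands on it immediately, so cross-solver sup-norm differences are
  `O(1e−2)` at the first 2–3 nodes and ≈ 4e−3 beyond them (`α = 0.8`,
  `T = 1`, `N = 200`).
- Lower orders jump harder at `t = 0` (larger `(1−α)/ABC[α]`) but decay
  more slowly afterwards (power-law memory), so at `t = 50` the prey
  density *increases* as `α` decreases, while the infected compartment
  grows more slowly at lower order. Prey and susceptible predators are
  monotone declining at `α ∈ {0.8, 1.0}` apart from the startup relaxation
  oscillation described above.

## Diagnostics

The Lipschitz constants are reproduced exactly as defined by the
analysis — `L₁ = b₁ + (b₁/k)(A₁+A₁*) + abC₁ + r₁D₁`,
`L₂ = (cb/(a+A₁))A₁ + dD₁ + m(C₁+C₁*)`, `L₃ = n + d + ckA₁` — with
sup-norm bounds defaulting to `max(1, initial density)` per species. They
are defined constants of the contraction argument, not claimed to be sharp
(the `abC₁` term in `L₁` in particular is taken as defined). The
contraction factors `Λ_ℓ`, perturbation constant
`κ = (Γ(α)−Γ(α+1)+T^α)/(ABC[α]Γ(α))` and Ulam–Hyers constants
`λ_ℓ = 2κ/(1−Λ_ℓ)` follow; `λ_ℓ` is reported as undefined when
`Λ_ℓ ≥ 1`. At `α = 1`, `T = 1`, `L = 0.5` these collapse to
`Λ = 0.5, κ = 1, λ = 4` (asserted exactly). Note that with the default
parameters `Λ₁ > 4` already at `T = 1`: the fixed-point guarantee does not
cover the default scenario horizon, which is consistent with the
instabilities observed above.

## Problem sizes

Defaults are chosen for a desk-scale machine: the scenario uses
`T = 100`, `N = 2000` (`Δ = 0.05`, full-history sums ≈ 2·10⁶ weight
multiplies per order), convergence studies use `N ≤ 800`, and the
classical-limit check `N = 4000` over `T = 10`. The entire test suite
runs in well under a minute.

## Known limitations

- Explicit local term: unconditional instability when
  `(1−α)/ABC[α]·|∂W/∂y| > 1` (see above); no implicit or
  predictor-corrector variant is provided.
- No positivity preservation: species densities may go slightly negative;
  the scenario runner warns (threshold −1e−12) and never clamps, because
  clamping would corrupt convergence measurements.
- Uniform grids only; no adaptive stepping; no short-memory acceleration.
- One-parameter Mittag-Leffler only; complex arguments unsupported.
- Two-parameter `E_{α,β}` appears only as a high-precision oracle inside
  tests, not as a public API.
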