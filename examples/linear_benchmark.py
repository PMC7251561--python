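"""Convergence of the fractional Adams-Bashforth stepper on the linear oracle.

The scalar problem ABC-D^alpha y = -y, y(0) = 1 has the closed-form
solution y(t) = (1/D) E_alpha((-alpha/B)/D * t^alpha), D = 1 + (1-alpha)/B,
which lets us measure the stepper's true error.  The error at T = 1 should
roughly halve each time the step count doubles (empirical order >= 1).

Caution demonstrated at the end: for small alpha the explicit local term
of the scheme is unstable regardless of step size.
"""

import numpy as np

from fracprey import (
    BlowUpError,
    FractionalOrder,
    LinearTestProblem,
    linear_abc_exact,
    solve_abm,
)

for alpha in (0.7, 1.0):
    order = FractionalOrder(alpha)
    problem = LinearTestProblem(lam=-1.0, y0=1.0, order=order)
    exact = linear_abc_exact(problem, 1.0)
    print(f"alpha = {alpha}: exact y(1) = {exact:.8f}")
    prev = None
    for n in (100, 200, 400, 800):
        traj = solve_abm(problem.rhs, np.float64(1.0), order, 1.0, n)
        err = abs(traj.states[-1] - exact)
        rate = f"  order {np.log2(prev / err):.2f}" if prev else ""
        print(f"  N = {n:4d}: error {err:.3e}{rate}")
        prev = err

# stability limit: (1 - alpha) |lam| / ABC[alpha] = 2.4 > 1 at alpha = 0.4
order = FractionalOrder(0.4)
problem = LinearTestProblem(lam=-1.0, y0=1.0, order=order)
try:
    solve_abm(problem.rhs, np.float64(1.0), order, 1.0, 800)
except BlowUpError as exc:
    print(f"\nalpha = 0.4 diverges as predicted: {exc}")
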