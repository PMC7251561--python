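"""Fractional Adams-Bashforth stepper, its weights, and the Picard oracle."""

import math

import numpy as np
import pytest

from fracprey import (
    BlowUpError,
    ContractionFailure,
    FractionalOrder,
    LinearTestProblem,
    ModelParams,
    Trajectory,
    ab_weights,
    diagnostics,
    linear_abc_exact,
    rhs,
    solve_abm,
    solve_picard,
)
from conftest import weight_integrals_quad


class TestWeights:
    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.8, 1.0])
    @pytest.mark.parametrize("n", [0, 4, 9])
    def test_last_panel_closed_form(self, n, alpha):
        a, b = ab_weights(n, n, alpha)
        assert a == pytest.approx(2.0 + alpha)
        assert b == pytest.approx(1.0)

    def test_classical_order_reduces_to_adams_bashforth(self):
        # at alpha = 1 every panel weight is (A, B) = (3, 1): the (3/2, -1/2)
        # classical two-step weights after division by Gamma(3) = 2
        for n in range(6):
            for ell in range(n + 1):
                assert ab_weights(n, ell, 1.0) == pytest.approx((3.0, 1.0))

    @pytest.mark.parametrize(
        "n, ell, alpha",
        [(2, 0, 0.4), (6, 3, 0.6), (10, 10, 0.5), (10, 9, 0.9), (5, 1, 0.3)],
    )
    def test_match_defining_integrals(self, n, ell, alpha):
        """A and B reproduce the exact panel integrals of the interpolation
        polynomial against the singular kernel (adaptive quadrature oracle)."""
        a, b = ab_weights(n, ell, alpha)
        scale = 1.0 / (alpha * (alpha + 1.0))
        ia, ib = weight_integrals_quad(n, ell, alpha)
        assert scale * a == pytest.approx(ia, abs=1e-10)
        assert scale * b == pytest.approx(ib, abs=1e-10)

    def test_positive_on_grid(self):
        for alpha in np.arange(0.1, 1.01, 0.1):
            for n in range(51):
                j = np.arange(n + 1, dtype=float)
                jp = np.where(j > 0, j, 1.0) ** alpha
                jp[0] = 0.0
                a = (j + 1.0) ** alpha * (j + 2.0 + alpha) - jp * (j + 2.0 + 2.0 * alpha)
                b = (j + 1.0) ** (alpha + 1.0) - jp * (j + 1.0 + alpha)
                assert np.all(a > 0.0) and np.all(b > 0.0)

    def test_invalid_indices_rejected(self):
        with pytest.raises(ValueError):
            ab_weights(2, 3, 0.5)
        with pytest.raises(ValueError):
            ab_weights(-1, 0, 0.5)
        with pytest.raises(ValueError):
            ab_weights(2, 1, 1.5)

    def test_history_prefactor_identity(self):
        """alpha/(B Gamma(a)) * dt^(a+1)/(a(a+1)) / dt equals
        alpha * dt^a/(B Gamma(a+2)) — the prefactor of the assembled
        scheme, where the leading alpha sits outside the weight sum.
        Guards the classic off-by-dt (and off-by-alpha) transcription
        errors when moving between the panel-integral and assembled forms."""
        dt = 0.037
        for alpha in (0.2, 0.5, 0.77, 1.0):
            b = alpha / (2.0 - alpha)
            lhs = alpha / (b * math.gamma(alpha)) * dt ** (alpha + 1.0) / (
                alpha * (alpha + 1.0)
            ) / dt
            rhs_ = alpha * dt**alpha / (b * math.gamma(alpha + 2.0))
            assert lhs == pytest.approx(rhs_, rel=1e-13)


class TestSolveABM:
    def test_zero_rhs_is_constant(self):
        traj = solve_abm(lambda t, y: 0.0 * y, np.array([1.0, -2.0]),
                         FractionalOrder(0.6), 1.0, 50)
        assert np.all(traj.states == [1.0, -2.0])
        assert traj.states.shape == (51, 2)

    def test_initial_condition_exact(self):
        traj = solve_abm(lambda t, y: -y, np.float64(0.7), FractionalOrder(0.8), 1.0, 10)
        assert traj.states[0] == 0.7

    def test_classical_exponential_decay(self):
        order = FractionalOrder(1.0)
        traj = solve_abm(lambda t, y: -y, np.float64(1.0), order, 5.0, 5000)
        exact = np.exp(-traj.grid)
        assert np.max(np.abs(traj.states - exact)) < 1e-3

    @pytest.mark.parametrize("alpha, min_order", [(0.7, 1.0), (1.0, 1.9)])
    def test_convergence_to_mittag_leffler_solution(self, alpha, min_order):
        """Error at T against the closed form decays with empirical order
        >= 1 (~order 1 for fractional, ~2 classical)."""
        order = FractionalOrder(alpha)
        prob = LinearTestProblem(-1.0, 1.0, order)
        exact = linear_abc_exact(prob, 1.0)
        errs = []
        for n in (100, 200, 400, 800):
            traj = solve_abm(prob.rhs, np.float64(1.0), order, 1.0, n)
            errs.append(abs(traj.states[-1] - exact))
        rates = [math.log2(errs[i] / errs[i + 1]) for i in range(3)]
        assert min(rates) >= min_order - 0.15

    def test_low_order_stiff_local_term_blows_up(self):
        """For (1-alpha)|lam|/ABC[alpha] > 1 the explicit local term makes
        the scheme unstable at any step size: alpha=0.4, lam=-1 gives
        amplification 2.4 per step and overflows within 800 steps."""
        order = FractionalOrder(0.4)
        prob = LinearTestProblem(-1.0, 1.0, order)
        with pytest.raises(BlowUpError) as exc:
            solve_abm(prob.rhs, np.float64(1.0), order, 1.0, 800)
        assert exc.value.step <= 800

    def test_deterministic_csv_bytes(self, params, tmp_path):
        f = lambda t, y: rhs(t, y, params)
        paths = []
        for tag in ("a", "b"):
            traj = solve_abm(f, params.initial_state, FractionalOrder(0.8), 1.0, 100)
            p = tmp_path / f"{tag}.csv"
            traj.to_csv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_csv_roundtrip(self, params, tmp_path):
        order = FractionalOrder(0.9)
        traj = solve_abm(lambda t, y: rhs(t, y, params), params.initial_state,
                         order, 1.0, 20)
        p = tmp_path / "traj.csv"
        traj.to_csv(p)
        assert p.read_text().splitlines()[0] == "t,P,S,I"
        back = Trajectory.from_csv(p, order)
        assert np.array_equal(back.states, traj.states)
        assert np.array_equal(back.grid, traj.grid)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            solve_abm(lambda t, y: -y, np.float64(1.0), FractionalOrder(0.5), 1.0, 0)
        with pytest.raises(ValueError):
            solve_abm(lambda t, y: -y, np.float64(1.0), FractionalOrder(0.5), -1.0, 10)


class TestSolvePicard:
    def test_zero_rhs_converges_immediately(self):
        traj = solve_picard(lambda t, y: 0.0 * y, np.array([2.0]),
                            FractionalOrder(0.7), 1.0, 10)
        assert traj.meta["iterations"] == 1
        assert traj.meta["achieved_diff"] == 0.0
        assert np.all(traj.states == 2.0)

    def test_successive_differences_bounded_by_contraction_factor(self, params):
        """On the linear fixture (lam=-0.5, alpha=0.8, T=1) the successive
        Picard differences decay geometrically with ratio at most the
        contraction factor Lambda computed with L = |lam|."""
        order = FractionalOrder(0.8)
        prob = LinearTestProblem(-0.5, 1.0, order)
        rep = diagnostics(params, order, 1.0, lipschitz_override=(0.5, 0.5, 0.5))
        assert rep.Lambda1 < 1.0
        traj = solve_picard(prob.rhs, np.float64(1.0), order, 1.0, 200,
                            max_iter=100, tol=1e-13)
        diffs = [d for d in traj.meta["diff_history"] if d > 1e-14]
        ratios = [b / a for a, b in zip(diffs, diffs[1:])]
        assert max(ratios) <= rep.Lambda1 + 1e-9

    def test_divergence_raises_contraction_failure(self):
        """alpha=0.4, lam=-1 violates the contraction condition
        (Lambda = 2.4 from the local term alone) and Picard must report it."""
        order = FractionalOrder(0.4)
        prob = LinearTestProblem(-1.0, 1.0, order)
        with pytest.raises(ContractionFailure, match="Lambda"):
            solve_picard(prob.rhs, np.float64(1.0), order, 1.0, 100, max_iter=50)

    def test_agrees_with_abm_away_from_startup_layer(self, params):
        """Cross-solver consistency on the three-species model (T=1,
        alpha=0.8): the two trajectories agree to 5e-3 once past the first
        three nodes.  At the startup layer they differ O(1e-2) because the
        kernels do not vanish at t=0, so the underlying Volterra solution
        jumps there; Picard lands on the jumped branch immediately while
        the explicit scheme relaxes onto it geometrically."""
        order = FractionalOrder(0.8)
        f = lambda t, y: rhs(t, y, params)
        ta = solve_abm(f, params.initial_state, order, 1.0, 200)
        tp = solve_picard(f, params.initial_state, order, 1.0, 200,
                          max_iter=200, tol=1e-12)
        assert np.max(np.abs(ta.states[3:] - tp.states[3:])) < 5e-3
        assert np.array_equal(ta.states[0], tp.states[0])
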