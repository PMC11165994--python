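import numpy as np
import pytest

from epiunwarp.geometry import FieldMap, ImageVolume, OppositePair
from epiunwarp.objective import LossConfig, evaluate
from epiunwarp.operators import diff_pe, solve_shifted_lap2d
from epiunwarp.optim import (
    OptimizerOptions,
    admm,
    armijo,
    block_pcg,
    gauss_newton,
    lbfgs,
    pcg,
)
from epiunwarp.simulate import make_case


class TestArmijo:
    def test_quadratic_accepts_newton_step(self):
        # J(x) = x^2 at x = 1; Newton step q = -g/J'' = -1
        opts = OptimizerOptions()
        hit = armijo(lambda x: float(x**2), np.array(1.0), np.array(-1.0),
                     np.array(2.0), opts)
        assert hit is not None
        gamma, J = hit
        assert gamma == 1.0 and J == 0.0

    def test_ascent_direction_rejected(self):
        with pytest.raises(ValueError):
            armijo(lambda x: float(x**2), np.array(1.0), np.array(1.0),
                   np.array(2.0), OptimizerOptions())

    def test_backtracks_past_barrier_wall(self):
        def f(x):
            x = float(x)
            return np.inf if x > 0.3 else (x - 0.3) ** 2

        opts = OptimizerOptions()
        hit = armijo(f, np.array(0.0), np.array(1.0), np.array(-0.6), opts, J0=f(0.0))
        assert hit is not None
        gamma, J = hit
        assert gamma <= 0.25
        assert J < f(0.0)


class TestPcg:
    def test_identity_system_one_iteration(self, rng):
        rhs = rng.standard_normal(20)
        x, k = pcg(lambda v: v, rhs)
        np.testing.assert_allclose(x, rhs, atol=1e-12)
        assert k == 1

    def test_diagonal_system_with_exact_preconditioner(self, rng):
        d = rng.random(15) + 0.5
        rhs = rng.standard_normal(15)
        x, k = pcg(lambda v: d * v, rhs, precond_diagonal=d)
        np.testing.assert_allclose(x, rhs / d, atol=1e-10)
        assert k == 1

    def test_matches_dense_solver_on_random_spd(self, rng):
        A = rng.standard_normal((30, 30))
        A = A @ A.T + 30 * np.eye(30)
        rhs = rng.standard_normal(30)
        x, _ = pcg(lambda v: A @ v, rhs, precond_diagonal=np.diag(A),
                   max_iters=60, rel_res=1e-10)
        expected = np.linalg.solve(A, rhs)
        assert np.linalg.norm(x - expected) / np.linalg.norm(expected) < 1e-8

    def test_respects_iteration_cap(self, rng):
        A = rng.standard_normal((30, 30))
        A = A @ A.T + 30 * np.eye(30)
        rhs = rng.standard_normal(30)
        _, k = pcg(lambda v: A @ v, rhs, max_iters=10, rel_res=1e-14)
        assert k == 10


class TestBlockPcg:
    def test_matches_per_column_dense_solves(self, rng):
        # column-separable SPD operator: a different tridiagonal per column
        n1, n2, m = 3, 2, 7
        mats = []
        for _ in range(n1 * n2):
            B = rng.standard_normal((m, m))
            mats.append(B @ B.T + m * np.eye(m))

        def matvec(x):
            out = np.empty_like(x)
            flat = x.reshape(-1, m)
            for i, A in enumerate(mats):
                out.reshape(-1, m)[i] = A @ flat[i]
            return out

        rhs = rng.standard_normal((n1, n2, m))
        diag = np.stack([np.diag(A) for A in mats]).reshape(n1, n2, m)
        x, _ = block_pcg(matvec, rhs, diag, max_iters=100, rel_res=1e-12)
        for i, A in enumerate(mats):
            expected = np.linalg.solve(A, rhs.reshape(-1, m)[i])
            got = x.reshape(-1, m)[i]
            assert np.linalg.norm(got - expected) / np.linalg.norm(expected) < 1e-8


@pytest.fixture(scope="module")
def small_case():
    return make_case((20, 20, 20), seed=0, max_slope=0.4)


class TestGaussNewton:
    def test_identical_pair_stays_at_zero(self, rng):
        data = rng.random((8, 8, 10)) + 0.1
        pair = OppositePair(ImageVolume(data), ImageVolume(data.copy()))
        res = gauss_newton(pair, FieldMap(np.zeros((8, 8, 11))))
        assert res.stop_reason == "grad"
        np.testing.assert_allclose(res.field.values, 0.0, atol=1e-10)

    def test_monotone_decrease_and_feasibility(self, small_case):
        from epiunwarp.otinit import initialize

        b0 = initialize(small_case.pair, blur=True)
        res = gauss_newton(small_case.pair, b0)
        Js = [h["J"] for h in res.history]
        assert all(b <= a for a, b in zip(Js, Js[1:]))
        assert np.abs(diff_pe(res.field)).max() < 1.0
        # optimization improves on the blurred initialization
        assert Js[-1] < Js[0]

    def test_infeasible_start_rejected(self, small_case):
        bad = np.zeros((20, 20, 21))
        bad[5, 5, 10] = 10.0
        with pytest.raises(ValueError):
            gauss_newton(small_case.pair, FieldMap(bad))


class TestLbfgs:
    def test_identical_pair_stays_at_zero(self, rng):
        data = rng.random((8, 8, 10)) + 0.1
        pair = OppositePair(ImageVolume(data), ImageVolume(data.copy()))
        res = lbfgs(pair, FieldMap(np.zeros((8, 8, 11))))
        assert res.stop_reason == "grad"
        np.testing.assert_allclose(res.field.values, 0.0, atol=1e-10)

    def test_minimizes_pure_regularizer(self):
        """With zero images the objective reduces to the convex regularizer
        alpha*S + beta*P, whose minimum value is 0 (flat fields); LBFGS must
        drive it there from a random feasible start."""
        shape = (6, 6, 8)
        pair = OppositePair(
            ImageVolume(np.zeros(shape) + 1e-12), ImageVolume(np.zeros(shape) + 1e-12)
        )
        from tests.conftest import random_feasible_field

        b0 = random_feasible_field(shape, (1.0, 1.0, 1.0), 0.3, seed=11)
        st0 = evaluate(pair, b0, LossConfig(), derivatives=False)
        res = lbfgs(pair, b0, opts=OptimizerOptions(
            max_outer_iters=300, tol_grad=1e-6, tol_loss_change=1e-12,
            tol_field_change=1e-12))
        stf = evaluate(pair, res.field, LossConfig(), derivatives=False)
        assert stf.J < 1e-6 * st0.J

    def test_monotone_decrease(self, small_case):
        from epiunwarp.otinit import initialize

        b0 = initialize(small_case.pair, blur=True)
        res = lbfgs(small_case.pair, b0)
        Js = [h["J"] for h in res.history]
        assert all(b <= a for a, b in zip(Js, Js[1:]))
        assert np.abs(diff_pe(res.field)).max() < 1.0


class TestAdmm:
    def test_identical_pair_is_fixed_point(self, rng):
        data = rng.random((8, 8, 10)) + 0.1
        pair = OppositePair(ImageVolume(data), ImageVolume(data.copy()))
        res = admm(pair, FieldMap(np.zeros((8, 8, 11))))
        assert res.stop_reason == "bzu-change"
        assert len(res.history) - 1 <= 2
        np.testing.assert_allclose(res.field.values, 0.0, atol=1e-10)

    def test_z_update_satisfies_normal_equations(self, rng):
        """The FFT z-update solves (alpha hv L12 + rho h3 I) z = rho h3 (b+u)
        exactly for the periodic cross-column Laplacian."""
        n1, n2, n3p1 = 6, 5, 4
        h1, h2, h3 = 1.1, 0.9, 1.3
        alpha, rho = 37.0, 220.0
        hv = h1 * h2 * h3
        b = rng.standard_normal((n1, n2, n3p1))
        u = rng.standard_normal((n1, n2, n3p1))
        z = solve_shifted_lap2d(rho * h3 * (b + u), alpha * hv, rho * h3,
                                spacings=(h1, h2))

        def lap12(x):
            out = np.zeros_like(x)
            for ax, h in ((0, h1), (1, h2)):
                out += (2 * x - np.roll(x, 1, axis=ax) - np.roll(x, -1, axis=ax)) / h**2
            return out

        resid = alpha * hv * lap12(z) + rho * h3 * z - rho * h3 * (b + u)
        assert np.linalg.norm(resid) / np.linalg.norm(rho * h3 * (b + u)) < 1e-10

    def test_reaches_gauss_newton_quality(self, small_case):
        from epiunwarp.otinit import initialize

        b0 = initialize(small_case.pair, blur=True)
        res_gn = gauss_newton(small_case.pair, b0)
        res_admm = admm(small_case.pair, b0)
        # consensus achieved and feasible
        assert np.abs(diff_pe(res_admm.field)).max() < 1.0
        j_gn = res_gn.history[-1]["J"]
        j_admm = res_admm.history[-1]["J"]
        assert j_admm <= 1.3 * j_gn  # same ballpark under default stopping
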