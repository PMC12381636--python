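"""Precision-program and debiasing tests.

The row programs are checked against a generic convex-programming oracle
(scipy SLSQP on the dense primal), closed forms in degenerate cases, the
strong-duality identity, and the bias-bound inequalities the constraint
set implies.
"""

import numpy as np
import pytest

from specdebias import (RegressionData, apply_transform, assemble_precision,
                        compute_spectral_transform, debias, default_mu,
                        fit_deconfounded, min_linf_residual,
                        solve_precision_row)
from specdebias.precision import PrecisionApprox, _dual_active_set
from conftest import slsqp_precision_row


def make(rng, n, p, rho=0.5, shrink=True):
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal(n)
    data = RegressionData(X=X, Y=Y)
    t = compute_spectral_transform(data, rho=rho, shrink=shrink)
    return data, t


class TestDefaultMu:
    def test_hand_evaluation(self):
        assert default_mu(500, 600) == pytest.approx(
            0.5 * np.sqrt(np.log(600) / 500), abs=1e-12)
        assert default_mu(500, 600, form="raw") == pytest.approx(
            0.5 * np.log(600) / 500, abs=1e-12)

    def test_monotone_decreasing_in_n(self):
        vals = [default_mu(n, 50) for n in (10, 100, 1000, 100_000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain(self):
        with pytest.raises(ValueError):
            default_mu(1, 10)


class TestClosedForms:
    def test_large_mu_returns_zero(self, rng):
        """mu >= 1 makes theta = 0 feasible with objective 0."""
        data, t = make(rng, 10, 6)
        theta, ok = solve_precision_row(data.X, t, 2, mu=1.0)
        assert ok and np.all(theta == 0.0)

    def test_orthonormal_design_closed_form(self):
        """Sigma_hat = I: the optimum is (1 - mu) e_j."""
        n = 6
        X = np.sqrt(n) * np.eye(n)
        data = RegressionData(X=X, Y=np.ones(n))
        t = compute_spectral_transform(data, rho=0.5, shrink=False)
        mu = 0.3
        theta, ok = solve_precision_row(X, t, 1, mu=mu)
        assert ok
        expect = np.zeros(n)
        expect[1] = 1.0 - mu
        assert np.allclose(theta, expect, atol=1e-9)
        M = X.T @ X
        assert theta @ M @ theta == pytest.approx((1 - mu) ** 2 * M[1, 1],
                                                  rel=1e-9)

    def test_scalar_case(self, rng):
        """p = 1: minimise theta^2 M subject to |1 - Sigma theta| <= mu."""
        X = rng.standard_normal((8, 1))
        data = RegressionData(X=X, Y=rng.standard_normal(8))
        t = compute_spectral_transform(data, rho=0.5, shrink=False)
        sig = float((X.T @ X)[0, 0]) / 8
        mu = 0.2
        theta, ok = solve_precision_row(X, t, 0, mu=mu)
        assert ok
        assert theta[0] == pytest.approx((1 - mu) / sig, rel=1e-8)


class TestOracle:
    @pytest.mark.parametrize("n,p,mu,shrink", [
        (15, 8, 0.3, True), (15, 8, 0.3, False),
        (12, 6, 0.15, True), (10, 12, 0.4, True), (20, 10, 0.05, False),
    ])
    def test_matches_generic_convex_solver(self, rng, n, p, mu, shrink):
        """Objective agrees with SLSQP on the dense primal to 1e-6 relative,
        and the recovered theta is feasible."""
        data, t = make(rng, n, p, shrink=shrink)
        j = 1
        theta, ok = solve_precision_row(data.X, t, j, mu=mu)
        assert ok
        _, f_oracle = slsqp_precision_row(data.X, t, j, mu)
        QX, _ = apply_transform(t, data)
        Sig = QX.T @ QX / n
        M = _objective_matrix(data.X, t)
        f_ours = float(theta @ M @ theta)
        assert f_ours <= f_oracle * (1 + 1e-6) + 1e-12
        assert abs(f_ours - f_oracle) <= 1e-6 * max(1.0, f_oracle)
        ej = np.zeros(p)
        ej[j] = 1.0
        assert np.max(np.abs(ej - Sig @ theta)) <= mu + 1e-6

    def test_strong_duality(self, rng):
        """Primal and dual optimal values coincide."""
        data, t = make(rng, 15, 9)
        n = 15
        G = data.X.T @ data.X
        mu = 0.25
        j = 0
        v, ok, _ = _dual_active_set(G, j, mu, n)
        assert ok
        primal = float(v @ G @ v) / (4 * n * n)
        dual = v[j] - primal - mu * float(np.abs(v).sum())
        assert primal == pytest.approx(dual, abs=1e-9)

    def test_objective_monotone_in_mu(self, rng):
        data, t = make(rng, 20, 8)
        M = _objective_matrix(data.X, t)
        vals = []
        for mu in (0.05, 0.1, 0.2, 0.4, 0.8):
            theta, ok = solve_precision_row(data.X, t, 0, mu=mu)
            assert ok
            vals.append(float(theta @ M @ theta))
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


def _dense_q4(t):
    from conftest import dense_q
    return np.linalg.matrix_power(dense_q(t), 4)


def _objective_matrix(X, t):
    return X.T @ _dense_q4(t) @ X


class TestBiasBounds:
    @pytest.mark.parametrize("shrink", [True, False])
    def test_constraint_implies_bounds(self, rng, shrink):
        """Every feasible row satisfies ||(I - Theta Sigma)_j||_inf <= mu,
        ||(Theta Sigma)_{j,-j}||_inf <= mu and |(Theta Sigma)_{jj}| <= 1+mu."""
        data, t = make(rng, 25, 10, shrink=shrink)
        mu = 0.3
        prec = assemble_precision(data.X, t, mu)
        assert not prec.fallback_identity
        QX, _ = apply_transform(t, data)
        Sig = QX.T @ QX / data.n
        TS = prec.Theta @ Sig
        R = np.eye(data.p) - TS
        for j in range(data.p):
            assert np.max(np.abs(R[j])) <= mu + 1e-6
            off = np.delete(TS[j], j)
            assert np.max(np.abs(off)) <= mu + 1e-6
            assert abs(TS[j, j]) <= 1 + mu + 1e-6


class TestInfeasibility:
    def test_rank_deficit_infeasible_row_triggers_global_fallback(self, rng):
        """With n << p and tiny mu the constraint set is empty and the
        whole matrix falls back to the identity."""
        data, t = make(rng, 4, 12)
        mu = 1e-4
        assert min_linf_residual(data.X.T @ data.X, 0, 4) > mu
        theta, ok = solve_precision_row(data.X, t, 0, mu=mu)
        assert not ok and theta is None
        prec = assemble_precision(data.X, t, mu, coords=[0, 1])
        assert prec.fallback_identity
        assert np.array_equal(prec.Theta, np.eye(12))

    def test_row_fallback_keeps_feasible_rows(self, rng):
        data, t = make(rng, 4, 12)
        prec = assemble_precision(data.X, t, 1e-4, coords=[0], fallback="row")
        assert not prec.fallback_identity
        assert prec.feasible[0] is False
        assert np.array_equal(prec.Theta, np.eye(12))

    def test_bad_args(self, rng):
        data, t = make(rng, 10, 5)
        with pytest.raises(IndexError):
            solve_precision_row(data.X, t, 7, mu=0.3)
        with pytest.raises(ValueError):
            solve_precision_row(data.X, t, 0, mu=0.0)


class TestDebias:
    def test_identity_theta_is_gradient_step(self, rng):
        data, t = make(rng, 20, 6)
        QX, QY = apply_transform(t, data)
        fit = fit_deconfounded(QX, QY, lam=0.1)
        prec = PrecisionApprox(Theta=np.eye(6), mu=0.5, feasible={},
                               fallback_identity=True, solved_coords=())
        est = debias(fit, prec, QX, QY)
        step = QX.T @ (QY - QX @ fit.beta_dec) / 20
        assert np.allclose(est.beta_hat, fit.beta_dec + step, atol=1e-12)
        assert np.allclose(est.beta_hat, est.beta_dec + est.correction)

    def test_zero_penalty_zero_correction(self, rng):
        """lam = 0 with n > p solves the normal equations: correction = 0."""
        data, t = make(rng, 30, 5, shrink=False)
        QX, QY = apply_transform(t, data)
        fit = fit_deconfounded(QX, QY, lam=0.0)
        prec = assemble_precision(data.X, t, mu=0.2)
        est = debias(fit, prec, QX, QY)
        assert np.allclose(est.correction, 0.0, atol=1e-8)
        assert np.allclose(est.beta_hat, fit.beta_dec, atol=1e-8)

    def test_exact_inverse_recovers_ols(self, rng):
        """Q = I, n > p, Theta = Sigma^-1 exactly: beta_hat is the OLS
        solution for every lambda (KKT-inversion algebra)."""
        X = rng.standard_normal((40, 6))
        Y = X @ np.array([1.0, 0.5, 0, 0, -1.0, 0]) + rng.standard_normal(40)
        data = RegressionData(X=X, Y=Y)
        t = compute_spectral_transform(data, rho=0.5, shrink=False)
        QX, QY = apply_transform(t, data)
        Sig = X.T @ X / 40
        prec = PrecisionApprox(Theta=np.linalg.inv(Sig), mu=0.0, feasible={},
                               fallback_identity=False, solved_coords=())
        ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
        for lam in (0.05, 0.2, 0.8):
            fit = fit_deconfounded(QX, QY, lam=lam)
            est = debias(fit, prec, QX, QY)
            assert np.allclose(est.beta_hat, ols, atol=1e-8)
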