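import json

import numpy as np
import pytest

from spherenf.model_core import (
    ConnectivityParams,
    DelayParams,
    FiringParams,
    ModelParams,
    calibrate_couplings,
    delay_profile,
    find_equilibria,
    firing_rate,
    firing_rate_derivative,
    kernel_mass,
    kernel_profile,
)


def closed_form_mass(conn: ConnectivityParams) -> float:
    """2 pi int_0^pi e^{-theta/sigma} sin(theta) dtheta has a closed form."""

    def one(sigma):
        a = 1.0 / sigma
        return (1.0 + np.exp(-a * np.pi)) / (1.0 + a * a)

    return 2.0 * np.pi * (
        conn.J1 * one(conn.sigma1) + conn.J2 * one(conn.sigma2)
    )


class TestFiringRate:
    def test_midpoint_and_limits(self):
        p = FiringParams(alpha=2.0, beta=4.0, delta=0.3)
        assert firing_rate(0.3, p) == pytest.approx(1.0)
        assert firing_rate(100.0, p) == pytest.approx(2.0)
        assert firing_rate(-100.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_overflow_safe(self):
        p = FiringParams(1.0, 50.0, 0.0)
        vals = firing_rate(np.array([-1e4, 1e4]), p)
        assert np.all(np.isfinite(vals))

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_derivatives_match_finite_differences(self, order):
        p = FiringParams(alpha=1.3, beta=3.7, delta=-0.2)
        u = np.linspace(-1.5, 1.5, 11)
        f = lambda x: firing_rate(x, p)
        if order == 1:
            h = 1e-6
            fd = (f(u + h) - f(u - h)) / (2.0 * h)
        elif order == 2:
            h = 1e-4
            fd = (f(u + h) - 2.0 * f(u) + f(u - h)) / h**2
        else:
            h = 1e-2
            fd = (
                -f(u - 2 * h) + 2 * f(u - h) - 2 * f(u + h) + f(u + 2 * h)
            ) / (2.0 * h**3)
        exact = firing_rate_derivative(u, p, order)
        # stencil truncation grows with the order; the exact closed form is
        # pinned separately by test_third_derivative_at_threshold
        tol = {1: 1e-8, 2: 1e-5, 3: 5e-3}[order]
        assert np.allclose(exact, fd, rtol=tol, atol=tol)

    def test_third_derivative_at_threshold(self):
        p = FiringParams(alpha=1.0, beta=4.0, delta=0.4172)
        # g = 1/2 at the threshold, so f''' = -alpha beta^3 / 8
        assert firing_rate_derivative(p.delta, p, 3) == pytest.approx(
            -p.alpha * p.beta**3 / 8.0
        )

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            firing_rate_derivative(0.0, FiringParams(1, 1, 0), 4)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FiringParams(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            FiringParams(1.0, 0.0, 0.0)


class TestKernelAndDelay:
    def test_profile_endpoints(self):
        conn = ConnectivityParams(2.0, -3.0, 1.0, 0.5)
        assert kernel_profile(1.0, conn) == pytest.approx(-1.0)
        expected = 2.0 * np.exp(-np.pi) - 3.0 * np.exp(-2.0 * np.pi)
        assert kernel_profile(-1.0, conn) == pytest.approx(expected)

    def test_delay_endpoints(self):
        d = DelayParams(3.0, 0.8)
        assert delay_profile(1.0, d) == pytest.approx(3.0)
        assert delay_profile(-1.0, d) == pytest.approx(3.0 + np.pi / 0.8)
        assert d.max_delay == pytest.approx(3.0 + np.pi / 0.8)

    def test_out_of_range_cosine_rejected(self):
        conn = ConnectivityParams(1.0, -1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            kernel_profile(1.5, conn)

    def test_roundoff_cosine_clamped(self):
        conn = ConnectivityParams(1.0, -1.0, 1.0, 0.5)
        val = kernel_profile(1.0 + 5e-13, conn)
        assert np.isfinite(val)

    def test_kernel_mass_closed_form(self):
        for conn in [
            ConnectivityParams(2.0, -3.0, 1.0, 0.5),
            ConnectivityParams(14.75, -25.69, 2.0 / 9.0, 1.0 / 6.0),
        ]:
            assert kernel_mass(conn) == pytest.approx(
                closed_form_mass(conn), rel=1e-10
            )

    def test_shape_property(self):
        assert ConnectivityParams(2.0, -1.0, 1.0, 0.5).shape == "wizard-hat"
        assert ConnectivityParams(1.0, -2.0, 1.0, 0.5).shape == "inverted"

    def test_sigma_order_warns(self):
        with pytest.warns(UserWarning):
            ConnectivityParams(1.0, -1.0, 0.5, 1.0)


class TestEquilibria:
    @staticmethod
    def _params(J1, J2, beta=4.0, delta=0.0, alpha=1.0):
        return ModelParams(
            FiringParams(alpha, beta, delta),
            ConnectivityParams(J1, J2, 1.0, 0.5),
            DelayParams(1.0, 1.0),
        )

    def test_roots_satisfy_fixed_point(self):
        p = self._params(2.0, -3.0)
        eqs = find_equilibria(p)
        assert eqs
        w0 = kernel_mass(p.connectivity)
        for eq in eqs:
            assert eq.w0 == pytest.approx(w0)
            assert abs(eq.u_hat - w0 * firing_rate(eq.u_hat, p.firing)) < 1e-10
            assert eq.kappa == pytest.approx(
                firing_rate_derivative(eq.u_hat, p.firing, 1)
            )

    def test_matches_dense_grid_oracle(self):
        p = self._params(3.0, -1.0, beta=10.0, delta=0.5)
        eqs = find_equilibria(p)
        w0 = kernel_mass(p.connectivity)

        grid = np.linspace(-abs(w0) - 1.0, abs(w0) + 1.0, 200001)
        resid = grid - w0 * firing_rate(grid, p.firing)
        oracle = int(np.sum(np.sign(resid[:-1]) * np.sign(resid[1:]) < 0))
        assert len([e for e in eqs if not e.fold_suspect]) == oracle

    def test_balanced_kernel_unique_zero(self):
        conn = ConnectivityParams(1.0, -1.0, 1.0, 0.5)
        ratio = closed_form_mass(ConnectivityParams(1.0, 0.0, 1.0, 0.5)) / (
            closed_form_mass(ConnectivityParams(0.0, 1.0, 1.0, 0.5))
        )
        balanced = ConnectivityParams(1.0, -ratio, 1.0, 0.5)
        p = ModelParams(FiringParams(1.0, 4.0, 0.1), balanced, DelayParams(1, 1))
        assert abs(kernel_mass(balanced)) < 1e-10
        eqs = find_equilibria(p)
        assert len(eqs) == 1
        assert eqs[0].u_hat == pytest.approx(0.0, abs=1e-10)
        del conn

    def test_steep_sigmoid_multiple_roots(self):
        # strong positive mass + steep sigmoid: three fixed points
        p = ModelParams(
            FiringParams(1.0, 30.0, 0.5),
            ConnectivityParams(1.0, 0.2, 1.0, 0.5),
            DelayParams(1.0, 1.0),
        )
        eqs = find_equilibria(p)
        assert len([e for e in eqs if not e.fold_suspect]) == 3


class TestCalibration:
    def test_roundtrip_to_lumped_gains(self, steep_firing):
        conn, eq = calibrate_couplings(
            29.50,
            -51.38,
            steep_firing,
            (2.0 / 9.0, 1.0 / 6.0),
            DelayParams(3.0, 0.8),
            select="leading",
        )
        assert eq.kappa * conn.J1 == pytest.approx(29.50, rel=1e-10)
        assert eq.kappa * conn.J2 == pytest.approx(-51.38, rel=1e-10)
        assert eq.residual < 1e-10
        # delta = 0 and near-balanced kernel: kappa close to alpha*beta/4
        assert eq.kappa == pytest.approx(2.0, rel=1e-3)

    def test_all_branches_consistent(self):
        firing = FiringParams(1.0, 4.0, 0.1)
        sols = calibrate_couplings(
            1.5, -4.0, firing, (1.0, 0.5), DelayParams(3.0, 1.0), select="all"
        )
        assert sols
        for conn, eq in sols:
            assert eq.kappa * conn.J1 == pytest.approx(1.5, rel=1e-10)
            assert eq.residual < 1e-10

    def test_zero_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_couplings(
                0.0, 0.0, FiringParams(1, 4, 0), (1.0, 0.5), DelayParams(1, 1)
            )


class TestModelParams:
    def test_json_roundtrip(self):
        p = ModelParams(
            FiringParams(1.08, 4.0, 0.1),
            ConnectivityParams(1.678, -4.367, 1.0, 0.5),
            DelayParams(3.483, 1.0),
        )
        doc = p.to_json()
        assert ModelParams.from_json(doc) == p
        assert set(json.loads(doc)) == {
            "alpha", "beta", "delta", "J1", "J2",
            "sigma1", "sigma2", "tau0", "c",
        }

    def test_delay_validation(self):
        with pytest.raises(ValueError):
            DelayParams(-0.1, 1.0)
        with pytest.raises(ValueError):
            DelayParams(1.0, 0.0)
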