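"""Unit and property tests for the unified rate law and its derivatives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycowave.models import (
    FULL,
    LOW_FLUX,
    KineticParams,
    effective_allosteric_constant,
    hill_coefficient,
    hill_coefficient_derivative,
    phi,
    phi_from_state_enumeration,
    reaction_derivatives,
    reaction_terms,
    selkov_limit_family,
    steady_state,
    true_allosteric_constant,
)


class TestPhi:
    def test_no_substrate_gives_zero_rate(self, mwc50):
        assert phi(mwc50, 0.0, 1.0) == 0.0

    def test_hill_activation_requires_product(self, selkov):
        assert phi(selkov, 1.0, 0.0) == 0.0

    def test_rate_at_steady_state_balances_supply(self, mwc50):
        ss = steady_state(mwc50)
        assert phi(mwc50, ss.alpha_s, ss.gamma_s) == pytest.approx(
            mwc50.nu / mwc50.sigma, rel=1e-12
        )
        assert phi(mwc50, ss.alpha_s, ss.gamma_s) == pytest.approx(0.0100, abs=5e-5)

    def test_negative_concentration_rejected(self, mwc50):
        with pytest.raises(ValueError):
            phi(mwc50, -0.1, 0.5)
        with pytest.raises(ValueError):
            phi(mwc50, 0.1, -0.5)

    def test_bounded_below_one_and_increasing_in_alpha(self, mwc50):
        alphas = np.linspace(0.0, 50.0, 200)
        vals = phi(mwc50, alphas, 0.7)
        assert np.all(vals >= 0.0) and np.all(vals < 1.0)
        assert np.all(np.diff(vals) > 0)


class TestStateEnumeration:
    def test_dimer_without_product(self):
        # only R_00/R_10 occupied: phi = alpha/(L + 1 + alpha)
        assert phi_from_state_enumeration(2, 1.0, 1.0, 0.0) == pytest.approx(
            1.0 / 3.0, rel=1e-14
        )

    def test_inactive_conformation_dominates_at_large_L(self):
        assert phi_from_state_enumeration(5, 1e12, 1.0, 1.0) < 1e-9

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 8),
        L=st.floats(1.0, 1e4),
        alpha=st.floats(0.0, 20.0),
        gamma=st.floats(0.0, 5.0),
    )
    def test_matches_unified_rate_law(self, n, L, alpha, gamma):
        p = KineticParams(nu=0.5, sigma=10.0, q=1.0, n=n, L=L, eps=1.0)
        assert phi_from_state_enumeration(n, L, alpha, gamma) == pytest.approx(
            phi(p, alpha, gamma), abs=1e-12, rel=1e-12
        )


class TestSteadyState:
    @pytest.mark.parametrize(
        "kwargs, alpha_expected",
        [
            (dict(nu=0.5, sigma=1770.0, q=1.0, n=8, L=1.0, eps=0.0), 0.073),
            (dict(nu=0.5, sigma=50.0, q=1.0, n=8, L=1e3, eps=1.0), 0.40),
            (dict(nu=0.5, sigma=60.0, q=1.0, n=8, L=1e3, eps=1.0), 0.34),
        ],
    )
    def test_reference_values(self, kwargs, alpha_expected):
        ss = steady_state(KineticParams(**kwargs))
        assert ss.gamma_s == 0.5
        assert ss.alpha_s == pytest.approx(alpha_expected, abs=5e-3)

    @pytest.mark.parametrize("flux_mode", [FULL, LOW_FLUX])
    def test_reaction_terms_vanish(self, flux_mode):
        p = KineticParams(nu=0.4, sigma=30.0, q=2.0, n=4, L=50.0, eps=0.7,
                          flux_mode=flux_mode)
        ss = steady_state(p)
        fa, fg = reaction_terms(p, ss.alpha_s, ss.gamma_s)
        assert abs(fa) <= 1e-10 and abs(fg) <= 1e-10

    def test_sigma_below_nu_rejected(self):
        with pytest.raises(ValueError):
            steady_state(KineticParams(nu=2.0, sigma=1.0, q=1.0, n=2))

    def test_uniqueness_in_alpha(self, mwc60):
        # phi is monotone in alpha, so f_alpha has a single sign change
        ss = steady_state(mwc60)
        alphas = np.linspace(1e-6, 50.0, 4000)
        fa = mwc60.nu - mwc60.sigma * phi(mwc60, alphas, ss.gamma_s)
        assert np.sum(np.diff(np.sign(fa)) != 0) == 1


def _fd_grad(f, x, y, h=1e-5):
    return (
        (f(x + h, y) - f(x - h, y)) / (2 * h),
        (f(x, y + h) - f(x, y - h)) / (2 * h),
    )


@pytest.mark.parametrize(
    "params",
    [
        KineticParams(nu=0.5, sigma=50.0, q=1.0, n=8, L=1e3, eps=1.0),
        KineticParams(nu=0.5, sigma=1770.0, q=1.0, n=8, L=1.0, eps=0.0),
        KineticParams(nu=0.3, sigma=5.0, q=2.0, n=3, L=10.0, eps=0.4),
        KineticParams(nu=0.5, sigma=1.0, q=1.0, n=8, L=1.0, eps=1.0,
                      flux_mode=LOW_FLUX),
        KineticParams(nu=0.5, sigma=2.0, q=1.0, n=1, L=1.0, eps=0.5),
    ],
)
class TestReactionDerivatives:
    def test_gradient_and_hessian_match_finite_differences(self, params):
        a0, g0 = 0.8, 0.6
        fa, fg = reaction_derivatives(params, a0, g0)
        for deriv, fval in ((fa, lambda a, g: reaction_terms(params, a, g)[0]),
                            (fg, lambda a, g: reaction_terms(params, a, g)[1])):
            ga, gg = _fd_grad(fval, a0, g0)
            assert deriv.grad[0] == pytest.approx(ga, rel=1e-6, abs=1e-8)
            assert deriv.grad[1] == pytest.approx(gg, rel=1e-6, abs=1e-8)
            # second partials via finite differences of the analytic gradient
            h = 1e-6

            def grad_of(a, g):
                d1, d2 = reaction_derivatives(params, a, g)
                return d1.grad if deriv is fa else d2.grad

            for j, (da, dg) in enumerate([(h, 0.0), (0.0, h)]):
                fd = (grad_of(a0 + da, g0 + dg) - grad_of(a0 - da, g0 - dg)) / (2 * h)
                np.testing.assert_allclose(deriv.hess[:, j], fd, rtol=1e-5, atol=1e-7)

    def test_third_order_matches_fd_of_hessian(self, params):
        a0, g0, h = 0.8, 0.6, 1e-6
        fa, _ = reaction_derivatives(params, a0, g0)

        def hess(a, g):
            return reaction_derivatives(params, a, g)[0].hess

        for k, (da, dg) in enumerate([(h, 0.0), (0.0, h)]):
            fd = (hess(a0 + da, g0 + dg) - hess(a0 - da, g0 - dg)) / (2 * h)
            np.testing.assert_allclose(fa.third[:, :, k], fd, rtol=1e-4, atol=1e-6)

    def test_symmetry_under_index_permutation(self, params):
        fa, fg = reaction_derivatives(params, 1.2, 0.9)
        for t in (fa.third, fg.third):
            assert np.allclose(t, np.transpose(t, (1, 0, 2)))
            assert np.allclose(t, np.transpose(t, (0, 2, 1)))
        assert np.allclose(fa.hess, fa.hess.T)

    def test_fgamma_proportional_to_falpha(self, params):
        fa, fg = reaction_derivatives(params, 0.5, 0.5)
        np.testing.assert_allclose(fg.hess, -params.q * fa.hess, rtol=1e-12)
        np.testing.assert_allclose(fg.third, -params.q * fa.third, rtol=1e-12)
        assert fg.grad[0] == pytest.approx(-params.q * fa.grad[0], rel=1e-12)
        assert fg.grad[1] == pytest.approx(-params.q * fa.grad[1] - 1.0, rel=1e-12)


def test_low_flux_is_linear_in_alpha(lowflux_selkov):
    fa, _ = reaction_derivatives(lowflux_selkov, 2.0, 0.7)
    assert fa.hess[0, 0] == 0.0
    assert fa.third[0, 0, 0] == 0.0 and fa.third[0, 0, 1] == 0.0


class TestHillCoefficient:
    def test_selkov_closed_form(self, selkov):
        # n/(1 + gamma^n): equals 4 at gamma = 1, n = 8
        assert hill_coefficient(selkov, 1.0) == pytest.approx(4.0, rel=1e-14)
        g = np.linspace(0.05, 3.0, 50)
        nh = hill_coefficient(selkov, g)
        assert np.all(np.diff(nh) < 0)
        assert np.all(np.sign(hill_coefficient_derivative(selkov, g)) <= 0)

    @pytest.mark.parametrize(
        "params",
        [
            KineticParams(nu=0.5, sigma=50.0, q=1.0, n=8, L=1e3, eps=1.0),
            KineticParams(nu=0.5, sigma=1770.0, q=1.0, n=8, L=1.0, eps=0.0),
            KineticParams(nu=0.3, sigma=5.0, q=2.0, n=3, L=10.0, eps=0.4),
        ],
    )
    def test_matches_log_derivative_definition(self, params):
        # definitional oracle: n_H = d log M / d log gamma, M = phi/(1-phi)
        for gamma in (0.2, 0.5, 1.0, 2.0):
            h = 1e-6 * gamma

            def logM(g):
                p = phi(params, 1.3, g)
                return math.log(p / (1.0 - p))

            oracle = gamma * (logM(gamma + h) - logM(gamma - h)) / (2 * h)
            assert hill_coefficient(params, gamma) == pytest.approx(
                oracle, rel=1e-6
            )

    def test_mwc_has_single_interior_maximum(self, mwc60):
        g = np.linspace(0.01, 5.0, 2000)
        nh = hill_coefficient(mwc60, g)
        i = int(np.argmax(nh))
        assert 0 < i < len(g) - 1
        signs = np.sign(np.diff(nh))
        # rises then falls, exactly one sign change
        assert np.sum(np.diff(signs) != 0) == 1


class TestSelkovLimitFamily:
    def test_eps_one_is_mwc(self):
        (p,) = selkov_limit_family(1e3, [1.0], n=8)
        assert p.L == 1e3 and p.eps == 1.0

    def test_true_allosteric_constant_diverges(self):
        assert true_allosteric_constant(1e3, 0.1, 8) == pytest.approx(
            100.9 / 1e-8, rel=1e-12
        )
        assert effective_allosteric_constant(1e3, 0.1) == pytest.approx(100.9)

    def test_uniform_convergence_to_hill_limit(self):
        hill = KineticParams(nu=0.5, sigma=10.0, q=1.0, n=8, L=1.0, eps=0.0)
        a = np.linspace(0.0, 3.0, 40)[:, None]
        g = np.linspace(0.0, 2.0, 40)[None, :]
        sups = []
        # L_eff = eps(L-1)+1, so the Hill limit needs eps << 1/(L-1)
        for eps in (1e-2, 1e-4, 1e-6):
            (p,) = selkov_limit_family(1e3, [eps], n=8, sigma=10.0)
            sups.append(np.max(np.abs(phi(p, a, g) - phi(hill, a, g))))
        assert sups[0] > sups[1] > sups[2]
        assert sups[2] < 1e-2

    def test_eps_zero_with_large_L_rejected(self):
        with pytest.raises(ValueError):
            selkov_limit_family(1e3, [0.0])


def test_params_config_roundtrip(mwc50):
    text = mwc50.to_config()
    assert KineticParams.from_config(text) == mwc50


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        KineticParams(nu=-1.0, sigma=2.0)
    with pytest.raises(ValueError):
        KineticParams(nu=0.5, sigma=2.0, eps=1.5)
    with pytest.raises(ValueError):
        KineticParams(nu=0.5, sigma=2.0, L=0.5)
    with pytest.raises(ValueError):
        KineticParams(nu=0.5, sigma=2.0, flux_mode="bogus")
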