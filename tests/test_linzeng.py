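"""Retrospective likelihood: quadrature oracles, cancellation, tests, surface."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.special import expit

from secophen.errors import ConfigurationError, ParameterError
from secophen.linzeng import (
    fit_retrospective,
    loglik_surface,
    lrt_beta1,
    retrospective_loglik,
    wald_test_beta1,
)
from secophen.simulate import calibrate_gamma0, simulate_case_control

from conftest import LOG2, LOG15, paper_params

PARAMS12 = dict(
    beta0=0.8, beta1=-0.2, sigma2=1.3, gamma0=-2.5, gamma1=0.3, gamma2=0.6
)
PX12 = np.array([0.5, 0.4, 0.1])


def brute_retrospective_loglik(ds, beta0, beta1, sigma2, gamma0, gamma1, gamma2, px,
                               order=256):
    """Independent per-subject implementation with high-order quadrature."""
    nodes, weights = np.polynomial.hermite.hermgauss(order)
    weights = weights / np.sqrt(np.pi)
    # P(D = 1) by explicit sum over levels and nodes
    rho = 0.0
    for k, v in enumerate(ds.level_values):
        for z, w in zip(nodes, weights):
            y = beta0 + beta1 * v + np.sqrt(2 * sigma2) * z
            rho += px[k] * w * expit(gamma0 + gamma1 * v + gamma2 * y)
    total = 0.0
    for i in range(ds.n):
        v = ds.level_values[ds.x[i]]
        pd = expit(gamma0 + gamma1 * v + gamma2 * ds.y[i])
        pd = pd if ds.d[i] == 1 else 1.0 - pd
        phi = np.exp(-((ds.y[i] - beta0 - beta1 * v) ** 2) / (2 * sigma2)) / np.sqrt(
            2 * np.pi * sigma2
        )
        marg = rho if ds.d[i] == 1 else 1.0 - rho
        total += np.log(pd) + np.log(phi) + np.log(px[ds.x[i]]) - np.log(marg)
    return total


class TestLoglik:
    def test_brute_force_oracle_fixture(self, fixture12):
        got = retrospective_loglik(fixture12, px=PX12, **PARAMS12)
        want = brute_retrospective_loglik(fixture12, px=PX12, **PARAMS12)
        assert got == pytest.approx(want, abs=1e-8)

    def test_quadrature_order_convergence(self, fixture12):
        vals = [
            retrospective_loglik(fixture12, px=PX12, quad_order=q, **PARAMS12)
            for q in (32, 64, 128)
        ]
        assert abs(vals[1] - vals[0]) < 1e-10
        assert abs(vals[2] - vals[1]) < 1e-10

    def test_ascertainment_cancels_when_gammas_zero(self, fixture12):
        # P(D|X,Y) = P(D) = expit(gamma0): retrospective = normal + multinomial
        params = dict(beta0=1.0, beta1=0.1, sigma2=0.9, gamma0=-1.2, gamma1=0.0,
                      gamma2=0.0)
        got = retrospective_loglik(fixture12, px=PX12, **params)
        resid = fixture12.y - params["beta0"] - params["beta1"] * fixture12.x_values
        want = float(
            -0.5 * fixture12.n * np.log(2 * np.pi * params["sigma2"])
            - resid @ resid / (2 * params["sigma2"])
            + np.log(PX12[fixture12.x]).sum()
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_invalid_simplex_rejected(self, fixture12):
        with pytest.raises(ParameterError):
            retrospective_loglik(fixture12, px=np.array([0.5, 0.6, 0.1]), **PARAMS12)

    def test_zero_prob_observed_level_floors(self, fixture12):
        val = retrospective_loglik(fixture12, px=np.array([0.0, 0.9, 0.1]), **PARAMS12)
        assert val == -1e15


class TestFitCancellation:
    def test_constrained_fit_matches_prospective_mle(self):
        # gamma1 = gamma2 = 0 held fixed: betas/sigma2 = OLS/MLE, px = empirical
        p = replace(paper_params(seed=71), gamma1=0.0, gamma2=0.0)
        ds = simulate_case_control(p.with_gamma0(calibrate_gamma0(p)))
        fit = fit_retrospective(ds, fixed={"gamma1": 0.0, "gamma2": 0.0}, seed=1)
        assert fit.converged
        v = ds.x_values
        X = np.column_stack([np.ones(ds.n), v])
        b = np.linalg.lstsq(X, ds.y, rcond=None)[0]
        s2 = float(np.sum((ds.y - X @ b) ** 2)) / ds.n
        counts = np.bincount(ds.x, minlength=ds.n_levels) / ds.n
        assert fit.beta0 == pytest.approx(b[0], abs=1e-5)
        assert fit.beta1 == pytest.approx(b[1], abs=1e-5)
        assert fit.sigma2 == pytest.approx(s2, abs=1e-5)
        np.testing.assert_allclose(fit.px, counts, atol=1e-5)


@pytest.fixture(scope="module")
def alt_fit(alt_dataset):
    return fit_retrospective(alt_dataset, seed=3)


class TestFitAndTests:
    def test_fit_converges_at_alternative(self, alt_fit):
        assert alt_fit.converged
        assert alt_fit.vcov is not None
        assert np.all(alt_fit.px >= 0) and alt_fit.px.sum() == pytest.approx(1.0)
        assert alt_fit.sigma2 > 0
        # vcov symmetric PSD
        np.testing.assert_allclose(alt_fit.vcov, alt_fit.vcov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(alt_fit.vcov) > -1e-10)

    def test_loglik_not_below_user_point(self, alt_dataset, alt_fit):
        # the fitted maximum dominates a nearby parameter point
        val = retrospective_loglik(
            alt_dataset, alt_fit.beta0 + 0.05, alt_fit.beta1, alt_fit.sigma2,
            alt_fit.gamma0, alt_fit.gamma1, alt_fit.gamma2, alt_fit.px,
        )
        assert alt_fit.loglik >= val

    def test_wald_arithmetic(self, alt_fit):
        res = wald_test_beta1(alt_fit)
        i = alt_fit.free_names.index("beta1")
        want = alt_fit.beta1 ** 2 / alt_fit.vcov[i, i]
        assert res.statistic == pytest.approx(want, rel=1e-12)
        assert res.df == 1

    def test_wald_requires_free_beta1(self, null_dataset):
        fit = fit_retrospective(null_dataset, fixed={"beta1": 0.0}, seed=0)
        with pytest.raises(ConfigurationError):
            wald_test_beta1(fit)

    def test_lrt_nonnegative_and_nested(self, alt_dataset):
        res = lrt_beta1(alt_dataset, seed=4)
        assert res.converged
        assert res.statistic >= 0.0
        assert res.df == 1

    def test_fixed_rate_constraint_holds(self, alt_dataset):
        from secophen.simulate import prevalence

        fit = fit_retrospective(alt_dataset, fixed_rate=0.05, seed=5)
        assert fit.converged
        rho = prevalence(
            fit.gamma0, fit.gamma1, fit.gamma2, fit.beta0, fit.beta1, fit.sigma2,
            alt_dataset.level_values, fit.px,
        )
        assert rho == pytest.approx(0.05, abs=1e-8)
        assert fit.constraint == "rate=0.05"

    def test_flat_flag_under_null(self):
        # null data with gamma1 = log 1.5: the weakly identified surface
        # should be flagged in a nontrivial fraction of replicates
        p = paper_params(gamma1=LOG15)
        params = p.with_gamma0(calibrate_gamma0(p))
        flags = 0
        for rep in range(5):
            ds = simulate_case_control(replace(params, seed=900 + rep))
            flags += fit_retrospective(ds, seed=rep).flat
        assert flags >= 1


class TestSurface:
    def test_1x1_grid_equals_loglik(self, fixture12):
        surf = loglik_surface(
            fixture12, ("beta0", "beta1"), [PARAMS12["beta0"]], [PARAMS12["beta1"]],
            fixed_params=PARAMS12, px=PX12,
        )
        want = retrospective_loglik(fixture12, px=PX12, **PARAMS12)
        assert surf.shape == (1, 1)
        assert surf[0, 0] == pytest.approx(want, abs=1e-12)

    def test_unknown_parameter(self, fixture12):
        with pytest.raises(ConfigurationError):
            loglik_surface(fixture12, ("beta0", "zeta"), [0], [0], fixed_params=PARAMS12)

    def test_beta_surface_peaked_gamma_surface_flat(self):
        p = paper_params(gamma1=LOG15)
        g0 = calibrate_gamma0(p)
        ds = simulate_case_control(replace(p.with_gamma0(g0), seed=321))
        truth = dict(beta0=1.0, beta1=0.0, sigma2=1.0, gamma0=g0, gamma1=LOG15,
                     gamma2=LOG2)
        px = np.array([0.49, 0.42, 0.09])
        b0g = np.linspace(0.5, 1.5, 11)
        b1g = np.linspace(-0.5, 0.5, 11)
        s_beta = loglik_surface(ds, ("beta0", "beta1"), b0g, b1g,
                                fixed_params=truth, px=px)
        i, j = np.unravel_index(np.argmax(s_beta), s_beta.shape)
        assert 0 < i < 10 and 0 < j < 10  # interior maximum
        g0g = np.linspace(g0 - 0.5, g0 + 0.5, 11)
        g1g = np.linspace(LOG15 - 0.5, LOG15 + 0.5, 11)
        s_gam = loglik_surface(ds, ("gamma0", "gamma1"), g0g, g1g,
                               fixed_params=truth, px=px)
        assert np.ptp(s_gam) < np.ptp(s_beta)


class TestRecoverySmoke:
    """Scaled-down parameter recovery (full 200-rep version in acceptance)."""

    def test_mean_beta1_near_truth(self):
        p = paper_params(beta1=-0.12, gamma1=LOG15)
        params = p.with_gamma0(calibrate_gamma0(p))
        betas = []
        for rep in range(20):
            ds = simulate_case_control(replace(params, seed=5_000 + rep))
            fit = fit_retrospective(ds, fixed_rate=0.05, seed=rep)
            assert fit.converged
            betas.append(fit.beta1)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) + 0.12) < 4 * mc_se
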