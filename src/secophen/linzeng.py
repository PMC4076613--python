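"""Retrospective-likelihood estimation for a normal secondary phenotype.

The likelihood of the observed ``(Y_i, X_i)`` pairs conditional on the
case-control sampling is::

    prod_i [ P(D_i | X_i, Y_i) * phi(Y_i; beta0 + beta1*X_i, sigma2) * p_{X_i}
             / P(D_i) ]

with a logistic disease model ``P(D=1|X,Y) = expit(gamma0 + gamma1*X +
gamma2*Y)``, a finite genotype-frequency simplex ``p`` over the observed
levels, and the marginal ``P(D=1)`` evaluated by Gauss-Hermite quadrature
(shared with :mod:`secophen.simulate`).

Maximization is by quasi-Newton iteration on an unconstrained scale
(``log sigma2``; softmax for the simplex) from a warm start, with multiple
jittered restarts.  Under the null hypothesis the surface can be nearly flat
in the disease-model directions, so near-ties in log-likelihood between
distant starts are detected and flagged rather than hidden, and
non-convergence is a reportable outcome.  The population disease rate can
optionally be held fixed during estimation, profiling ``gamma0`` out by
root finding at every evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq, minimize
from scipy.special import expit, log_expit

from .data_io import CaseControlDataset, TestResult
from .errors import CalibrationError, ConfigurationError, DataError, ParameterError
from .simulate import GH_ORDER, _gh_nodes, prevalence

__all__ = [
    "RetrospectiveFit",
    "retrospective_loglik",
    "fit_retrospective",
    "wald_test_beta1",
    "lrt_beta1",
    "loglik_surface",
]

_SCALAR_NAMES = ("beta0", "beta1", "sigma2", "gamma0", "gamma1", "gamma2")
_LOGLIK_FLOOR = -1e15
_BAD_NLL = 1e15


@dataclass
class RetrospectiveFit:
    """MLE of the retrospective model with variance estimates.

    ``vcov`` is the inverse observed information on the *free* parameters in
    ``free_names`` order; ``sigma2`` appears there as ``log_sigma2`` and the
    genotype simplex as softmax logits ``q1..qJ``.  ``constraint`` is
    ``"none"`` or ``"rate=<value>"`` when the disease rate was held fixed.
    """

    beta0: float
    beta1: float
    sigma2: float
    gamma0: float
    gamma1: float
    gamma2: float
    px: np.ndarray
    loglik: float
    vcov: np.ndarray | None
    free_names: tuple[str, ...]
    converged: bool
    constraint: str = "none"
    flat: bool = False
    gradient_norm: float = float("nan")
    n_starts_converged: int = 0
    n: int = 0
    notes: str = ""

    def se(self, name: str) -> float:
        """Standard error of a free parameter (transformed scale)."""
        if self.vcov is None:
            raise ValueError("vcov unavailable: " + self.notes)
        i = self.free_names.index(name)
        return float(np.sqrt(self.vcov[i, i]))


def retrospective_loglik(
    dataset: CaseControlDataset,
    beta0: float,
    beta1: float,
    sigma2: float,
    gamma0: float,
    gamma1: float,
    gamma2: float,
    px: np.ndarray,
    quad_order: int = GH_ORDER,
) -> float:
    """Retrospective log-likelihood at a given parameter point.

    Returns ``sum_i [log P(D_i|X_i,Y_i) + log phi(Y_i; beta0+beta1*X_i,
    sigma2) + log p_{X_i} - log P(D_i)]``.  An observed genotype level with
    zero probability yields the log-domain floor ``-1e15`` rather than
    ``-inf`` so optimizers can recover.
    """
    px = np.asarray(px, dtype=float)
    if px.shape[0] != dataset.n_levels or np.any(px < 0) or abs(px.sum() - 1.0) > 1e-8:
        raise ParameterError("px must be a probability simplex over the genotype levels")
    if sigma2 <= 0:
        raise ParameterError("sigma2 must be positive")
    if np.any(px[np.unique(dataset.x)] <= 0):
        return _LOGLIK_FLOOR
    v = dataset.x_values
    d = dataset.d
    y = dataset.y
    eta = gamma0 + gamma1 * v + gamma2 * y
    ll = float(np.sum(np.where(d == 1, log_expit(eta), log_expit(-eta))))
    resid = y - beta0 - beta1 * v
    ll += float(-0.5 * dataset.n * np.log(2.0 * np.pi * sigma2) - resid @ resid / (2.0 * sigma2))
    ll += float(np.log(px[dataset.x]).sum())
    rho = prevalence(
        gamma0, gamma1, gamma2, beta0, beta1, sigma2,
        dataset.level_values, px, order=quad_order,
    )
    n1 = dataset.n_cases
    ll -= n1 * np.log(rho) + (dataset.n - n1) * np.log1p(-rho)
    return ll


def _loglik_grad_natural(dataset, values, px, quad_order, skip_ascertainment=False):
    """Log-likelihood and its gradient on the natural parameter scale.

    Returns ``(ll, grad_scalars, grad_px)`` where ``grad_scalars`` follows
    ``_SCALAR_NAMES`` order (derivative w.r.t. sigma2 itself, not its log).
    With ``skip_ascertainment`` the ``-sum log P(D_i)`` term and its
    gradient are omitted (used when the disease rate is held fixed, where
    that term is constant).
    """
    v = dataset.x_values
    d = dataset.d
    y = dataset.y
    n = dataset.n
    n1 = dataset.n_cases
    beta0, beta1 = values["beta0"], values["beta1"]
    sigma2 = values["sigma2"]
    gamma0, gamma1, gamma2 = values["gamma0"], values["gamma1"], values["gamma2"]

    eta = gamma0 + gamma1 * v + gamma2 * y
    mu = expit(eta)
    ll = float(np.sum(np.where(d == 1, log_expit(eta), log_expit(-eta))))
    resid = y - beta0 - beta1 * v
    ll += float(-0.5 * n * np.log(2.0 * np.pi * sigma2) - resid @ resid / (2.0 * sigma2))
    counts = np.bincount(dataset.x, minlength=dataset.n_levels).astype(float)
    ll += float(counts @ np.log(px))

    dmu = d - mu
    g = {
        "beta0": float(resid.sum() / sigma2),
        "beta1": float(resid @ v / sigma2),
        "sigma2": float(-0.5 * n / sigma2 + resid @ resid / (2.0 * sigma2 ** 2)),
        "gamma0": float(dmu.sum()),
        "gamma1": float(dmu @ v),
        "gamma2": float(dmu @ y),
    }
    g_px = counts / np.maximum(px, 1e-300)

    # ascertainment term: -[n1 log rho + n0 log(1 - rho)]
    nodes, weights = _gh_nodes(quad_order)
    lv = dataset.level_values[:, None]
    yq = beta0 + beta1 * lv + np.sqrt(2.0 * sigma2) * nodes[None, :]
    muq = expit(gamma0 + gamma1 * lv + gamma2 * yq)
    S = muq @ weights                      # E[expit | X = level]
    rho = float(px @ S)
    cq = muq * (1.0 - muq)
    c0 = cq @ weights                      # per-level E[mu(1-mu)]
    drho = {
        "gamma0": float(px @ c0),
        "gamma1": float(px @ (c0 * lv[:, 0])),
        "gamma2": float(px @ ((cq * yq) @ weights)),
        "beta0": gamma2 * float(px @ c0),
        "beta1": gamma2 * float(px @ (c0 * lv[:, 0])),
        "sigma2": gamma2 * float(px @ ((cq * nodes[None, :]) @ weights))
        * np.sqrt(2.0) / (2.0 * np.sqrt(sigma2)),
    }
    if not skip_ascertainment:
        ll -= n1 * np.log(rho) + (n - n1) * np.log1p(-rho)
        m = n1 / rho - (n - n1) / (1.0 - rho)
        for k in g:
            g[k] -= m * drho[k]
        g_px = g_px - m * S
    return ll, g, g_px, rho, drho, S


class _Model:
    """Unconstrained parameterization of the retrospective likelihood.

    Free scalar parameters are a subset of ``(beta0, beta1, log_sigma2,
    gamma0, gamma1, gamma2)`` followed by the simplex logits ``q1..qJ``
    (level 0 is the softmax reference).  ``fixed`` pins scalar parameters at
    given values; ``fixed_rate`` removes ``gamma0`` from the free set and
    recovers it at every evaluation by solving ``P(D=1) = rate``.
    """

    def __init__(
        self,
        dataset: CaseControlDataset,
        fixed: Mapping[str, float] | None = None,
        fixed_rate: float | None = None,
        quad_order: int = GH_ORDER,
    ) -> None:
        self.ds = dataset
        self.v = dataset.x_values
        self.quad_order = quad_order
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(_SCALAR_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown fixed parameters: {sorted(unknown)}")
        self.fixed_rate = fixed_rate
        if fixed_rate is not None and "gamma0" in self.fixed:
            raise ConfigurationError("cannot both fix gamma0 and fix the disease rate")
        self.free_scalars = [
            n for n in _SCALAR_NAMES
            if n not in self.fixed and not (n == "gamma0" and fixed_rate is not None)
        ]
        self.n_q = dataset.n_levels - 1
        self.free_names = tuple(
            ("log_sigma2" if n == "sigma2" else n) for n in self.free_scalars
        ) + tuple(f"q{j}" for j in range(1, self.n_q + 1))
        self.n_free = len(self.free_names)

    # --- packing -----------------------------------------------------------
    def pack(self, values: Mapping[str, float], px: np.ndarray) -> np.ndarray:
        theta = []
        for n in self.free_scalars:
            theta.append(np.log(values[n]) if n == "sigma2" else values[n])
        px = np.clip(np.asarray(px, dtype=float), 1e-10, None)
        theta.extend(np.log(px[1:] / px[0]))
        return np.array(theta)

    def unpack(self, theta: np.ndarray) -> tuple[dict, np.ndarray]:
        values = dict(self.fixed)
        for i, n in enumerate(self.free_scalars):
            values[n] = float(np.exp(theta[i])) if n == "sigma2" else float(theta[i])
        q = theta[len(self.free_scalars):]
        logits = np.concatenate([[0.0], q])
        logits -= logits.max()
        px = np.exp(logits)
        px /= px.sum()
        return values, px

    def _gamma0_for(self, values: dict, px: np.ndarray) -> float:
        """Solve P(D=1) = fixed_rate for gamma0 (monotone; Newton + bisection fallback).

        The previous solution is reused as the Newton start, which makes the
        per-iterate profiling cheap during optimization.
        """
        target = self.fixed_rate
        nodes, weights = _gh_nodes(self.quad_order)
        lv = self.ds.level_values[:, None]
        yq = values["beta0"] + values["beta1"] * lv + np.sqrt(2.0 * values["sigma2"]) * nodes
        base = values["gamma1"] * lv + values["gamma2"] * yq

        def rho_and_slope(g0: float) -> tuple[float, float]:
            mu = expit(g0 + base)
            return float(px @ (mu @ weights)), float(px @ ((mu * (1.0 - mu)) @ weights))

        g0 = getattr(self, "_gamma0_cache", np.log(target / (1.0 - target)))
        for _ in range(50):
            rho, slope = rho_and_slope(g0)
            if abs(rho - target) < 1e-12:
                self._gamma0_cache = g0
                return g0
            if slope <= 0:
                break
            step = (target - rho) / slope
            g0 += np.clip(step, -5.0, 5.0)
            if abs(g0) > 50.0:
                raise CalibrationError("gamma0 profile left [-50, 50] on the logit scale")
        g0 = float(brentq(lambda g: rho_and_slope(g)[0] - target, -50.0, 50.0, xtol=1e-12))
        self._gamma0_cache = g0
        return g0

    def loglik_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood and analytic gradient on the free transformed scale."""
        values, px = self.unpack(theta)
        if self.fixed_rate is not None:
            values["gamma0"] = self._gamma0_for(values, px)
            ll, g, g_px, rho, drho, S = _loglik_grad_natural(
                self.ds, values, px, self.quad_order, skip_ascertainment=True
            )
            # the rate is pinned, so the ascertainment term is a constant ...
            n1 = self.ds.n_cases
            ll -= n1 * np.log(self.fixed_rate) + (self.ds.n - n1) * np.log1p(-self.fixed_rate)
            # ... but gamma0 is an implicit function of the rest:
            # d gamma0 / d psi = -(d rho / d psi) / (d rho / d gamma0)
            a = g["gamma0"] / drho["gamma0"]
            for k in g:
                if k != "gamma0":
                    g[k] = g[k] - a * drho[k]
            g_px = g_px - a * S
        else:
            ll, g, g_px, _, _, _ = _loglik_grad_natural(
                self.ds, values, px, self.quad_order
            )
        grad = np.empty(self.n_free)
        for i, name in enumerate(self.free_scalars):
            grad[i] = g[name] * values["sigma2"] if name == "sigma2" else g[name]
        # softmax chain rule for the simplex logits (level 0 is the reference)
        g_dot = float(px @ g_px)
        grad[len(self.free_scalars):] = px[1:] * (g_px[1:] - g_dot)
        return ll, grad

    def loglik(self, theta: np.ndarray) -> float:
        return self.loglik_and_grad(theta)[0]

    def negloglik_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            ll, grad = self.loglik_and_grad(theta)
        except (CalibrationError, FloatingPointError, OverflowError):
            return _BAD_NLL, np.zeros(self.n_free)
        if not np.isfinite(ll) or not np.all(np.isfinite(grad)):
            return _BAD_NLL, np.zeros(self.n_free)
        return -ll, -grad

    def grad(self, theta: np.ndarray) -> np.ndarray:
        return self.loglik_and_grad(theta)[1]


def _warm_start(dataset: CaseControlDataset) -> tuple[dict, np.ndarray]:
    """Cheap consistent-ish starting values: OLS, prospective logistic, empirical px."""
    v = dataset.x_values
    X = np.column_stack([np.ones(dataset.n), v])
    beta, _, _, _ = np.linalg.lstsq(X, dataset.y, rcond=None)
    resid = dataset.y - X @ beta
    sigma2 = max(float(resid @ resid) / dataset.n, 1e-6)
    gam = _logistic_irls(np.column_stack([np.ones(dataset.n), v, dataset.y]), dataset.d)
    counts = np.bincount(dataset.x, minlength=dataset.n_levels).astype(float)
    px = counts / counts.sum()
    values = {
        "beta0": float(beta[0]),
        "beta1": float(beta[1]),
        "sigma2": sigma2,
        "gamma0": float(gam[0]),
        "gamma1": float(gam[1]),
        "gamma2": float(gam[2]),
    }
    return values, px


def _logistic_irls(X: np.ndarray, d: np.ndarray, n_iter: int = 30) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        mu = expit(X @ beta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        try:
            step = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (d - mu))
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.clip(beta, -30, 30)


def fit_retrospective(
    dataset: CaseControlDataset,
    fixed_rate: float | None = None,
    init: Mapping[str, float] | None = None,
    fixed: Mapping[str, float] | None = None,
    n_starts: int = 5,
    jitter: float = 0.25,
    quad_order: int = GH_ORDER,
    seed: int = 0,
    gtol: float = 1e-5,
    max_iter: int = 500,
) -> RetrospectiveFit:
    """Maximize the retrospective likelihood by multi-start quasi-Newton.

    Parameters
    ----------
    fixed_rate : float, optional
        Hold the population disease rate at this value; ``gamma0`` is then
        profiled out by root finding at every iterate.
    init : mapping, optional
        Starting values overriding the warm start (keys among ``beta0``,
        ``beta1``, ``sigma2``, ``gamma0``, ``gamma1``, ``gamma2``).
    fixed : mapping, optional
        Pin scalar parameters (e.g. ``{"beta1": 0.0}`` for the null fit of
        the likelihood-ratio test).
    n_starts : int
        One warm start plus ``n_starts - 1`` jittered restarts; the best
        converged log-likelihood wins.  A near-tie in log-likelihood
        (< 1e-4) between starts that disagree in parameters (> 1e-2) raises
        the ``flat`` flag — the hallmark of the null-hypothesis surface.
    """
    if dataset.n_cases == 0 or dataset.n_controls == 0:
        raise DataError("both disease classes are required")
    if np.unique(dataset.x).shape[0] < 2:
        raise DataError("fewer than 2 occupied genotype levels")
    model = _Model(dataset, fixed=fixed, fixed_rate=fixed_rate, quad_order=quad_order)
    warm_values, warm_px = _warm_start(dataset)
    if init:
        warm_values.update(init)
    theta0 = model.pack(warm_values, warm_px)

    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + jitter * rng.standard_normal(theta0.shape) for _ in range(n_starts - 1)
    ]

    best = None
    solutions: list[tuple[float, np.ndarray]] = []
    n_ok = 0
    for s in starts:
        res = minimize(
            model.negloglik_and_grad, s, method="L-BFGS-B", jac=True,
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": gtol},
        )
        if not np.isfinite(res.fun) or res.fun >= _BAD_NLL:
            continue
        gnorm = float(np.max(np.abs(res.jac)))
        ok = bool(res.success) and gnorm < 1e-3
        if ok:
            n_ok += 1
        solutions.append((-res.fun, res.x))
        if ok and (best is None or -res.fun > best[0]):
            best = (-res.fun, res.x, gnorm)

    if best is None:
        # fall back to the best stationary-ish point, flagged non-converged
        if not solutions:
            raise CalibrationError("all starts failed to evaluate the likelihood")
        ll, th = max(solutions, key=lambda t: t[0])
        values, px = model.unpack(th)
        if fixed_rate is not None:
            values["gamma0"] = model._gamma0_for(values, px)
        return RetrospectiveFit(
            **{k: values[k] for k in _SCALAR_NAMES}, px=px, loglik=ll, vcov=None,
            free_names=model.free_names, converged=False,
            constraint="none" if fixed_rate is None else f"rate={fixed_rate}",
            n_starts_converged=0, n=dataset.n, notes="no start converged",
        )

    ll_best, theta_best, gnorm = best
    # flat surface: distinct stationary points with near-identical loglik ...
    flat = any(
        ll_best - ll < 1e-4 and np.max(np.abs(th - theta_best)) > 1e-2
        for ll, th in solutions
        if th is not theta_best
    )
    values, px = model.unpack(theta_best)
    if fixed_rate is not None:
        values["gamma0"] = model._gamma0_for(values, px)

    vcov, vnote, min_curvature = _observed_information_inverse(model, theta_best)
    # ... or curvature so low that moving > 1e-2 in some direction changes
    # the loglik by < 1e-4 (same thresholds as the multi-start tie rule)
    if min_curvature is not None and min_curvature < 2e-4 / 1e-2 ** 2:
        flat = True
    return RetrospectiveFit(
        **{k: values[k] for k in _SCALAR_NAMES}, px=px, loglik=ll_best, vcov=vcov,
        free_names=model.free_names, converged=True,
        constraint="none" if fixed_rate is None else f"rate={fixed_rate}",
        flat=flat, gradient_norm=gnorm, n_starts_converged=n_ok, n=dataset.n,
        notes=vnote,
    )


def _observed_information_inverse(model: _Model, theta: np.ndarray, step: float = 1e-5):
    """Inverse observed information at ``theta``.

    The Hessian of the negative log-likelihood is formed by central
    differencing of the analytic gradient (step 1e-5 on the transformed
    scale), then symmetrized and inverted.
    """
    k = theta.shape[0]
    h = step * np.maximum(1.0, np.abs(theta))
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[:, i] = (model.grad(theta - ei) - model.grad(theta + ei)) / (2.0 * h[i])
    H = 0.5 * (H + H.T)
    min_curvature = float(np.linalg.eigvalsh(H)[0])
    if np.linalg.cond(H) > 1e12:
        return None, "ill-conditioned observed information; vcov unavailable", min_curvature
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None, "singular observed information; vcov unavailable", min_curvature
    if np.any(np.diag(vcov) <= 0):
        return None, "observed information not positive definite; vcov unavailable", min_curvature
    return 0.5 * (vcov + vcov.T), "", min_curvature


def wald_test_beta1(fit: RetrospectiveFit) -> TestResult:
    """Wald chi-squared (1 df) test of the genotype effect on the trait."""
    if "beta1" not in fit.free_names:
        raise ConfigurationError("beta1 was fixed in this fit; no Wald test")
    if not fit.converged or fit.vcov is None:
        return TestResult(
            "linzeng_wald", float("nan"), 1, float("nan"), fit.n,
            converged=False, notes=fit.notes or "fit not converged",
        )
    var = fit.vcov[fit.free_names.index("beta1"), fit.free_names.index("beta1")]
    stat = fit.beta1 ** 2 / var
    return TestResult(
        "linzeng_wald", float(stat), 1, float(stats.chi2.sf(stat, 1)), fit.n,
        converged=True, notes="flat surface" if fit.flat else "",
    )


def lrt_beta1(
    dataset: CaseControlDataset,
    fixed_rate: float | None = None,
    **fit_kwargs,
) -> TestResult:
    """Likelihood-ratio chi-squared (1 df) test of ``beta1 = 0``.

    Both fits share the quadrature order and restart protocol.
    """
    full = fit_retrospective(dataset, fixed_rate=fixed_rate, **fit_kwargs)
    null = fit_retrospective(
        dataset, fixed_rate=fixed_rate, fixed={"beta1": 0.0}, **fit_kwargs
    )
    if not (full.converged and null.converged):
        return TestResult(
            "linzeng_lrt", float("nan"), 1, float("nan"), dataset.n,
            converged=False,
            notes="full fit" * (not full.converged) + " null fit" * (not null.converged)
            + " non-converged",
        )
    stat = 2.0 * (full.loglik - null.loglik)
    notes = "flat surface" if (full.flat or null.flat) else ""
    if stat < 0:
        notes = (notes + "; " if notes else "") + f"negative LRT {stat:.2e} clamped"
        stat = 0.0
    return TestResult(
        "linzeng_lrt", float(stat), 1, float(stats.chi2.sf(stat, 1)), dataset.n,
        converged=True, notes=notes,
    )


def loglik_surface(
    dataset: CaseControlDataset,
    param_pair: Sequence[str],
    grid1: np.ndarray,
    grid2: np.ndarray,
    fixed_params: Mapping[str, float] | None = None,
    px: np.ndarray | None = None,
    profile_others: bool = False,
    quad_order: int = GH_ORDER,
) -> np.ndarray:
    """Log-likelihood over a Cartesian grid of two named parameters.

    With ``profile_others=False`` (the default) the remaining parameters are
    held at ``fixed_params`` (and ``px``, defaulting to the empirical
    genotype frequencies); with ``True`` they are re-maximized at every grid
    point.  Returns a ``(len(grid1), len(grid2))`` matrix.
    """
    p1, p2 = param_pair
    for p in (p1, p2):
        if p not in _SCALAR_NAMES:
            raise ConfigurationError(f"unknown parameter {p!r}; choose from {_SCALAR_NAMES}")
    fixed_params = dict(fixed_params or {})
    if px is None:
        counts = np.bincount(dataset.x, minlength=dataset.n_levels).astype(float)
        px = counts / counts.sum()
    out = np.empty((len(grid1), len(grid2)))
    for i, a in enumerate(np.asarray(grid1, dtype=float)):
        for j, b in enumerate(np.asarray(grid2, dtype=float)):
            point = fixed_params | {p1: float(a), p2: float(b)}
            if profile_others:
                fit = fit_retrospective(dataset, fixed=point, quad_order=quad_order)
                out[i, j] = fit.loglik
            else:
                missing = [n for n in _SCALAR_NAMES if n not in point]
                if missing:
                    raise ConfigurationError(f"fixed_params missing {missing}")
                out[i, j] = retrospective_loglik(
                    dataset, point["beta0"], point["beta1"], point["sigma2"],
                    point["gamma0"], point["gamma1"], point["gamma2"], px,
                    quad_order=quad_order,
                )
    return out
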