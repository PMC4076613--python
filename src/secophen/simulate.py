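"""Ascertained case-control simulator for a quantitative secondary trait.

Generative model: genotype X is drawn from Hardy-Weinberg frequencies for a
minor-allele frequency ``maf``; the secondary trait is
``Y | X ~ Normal(beta0 + beta1 * X, sigma2)``; disease status follows the
logistic model ``P(D=1 | X, Y) = expit(gamma0 + gamma1 * X + gamma2 * Y)``.
Case-control ascertainment retains population draws until the case and
control quotas are both filled.

The population disease rate implied by the parameters is computed by
Gauss-Hermite quadrature over Y (the trait is normal, so the logistic x
Gaussian integrand is smooth and 64 nodes are ample), and ``gamma0`` can be
calibrated by root finding so the rate hits a target such as 1% or 5%.

Randomness uses ``numpy.random.Generator`` (PCG64).  Within each sampling
block the draw order is fixed - the X block, then the Y block, then the D
block - so datasets are reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data_io import CaseControlDataset
from .errors import CalibrationError, ConfigurationError, FeasibilityError, ParameterError

__all__ = [
    "SimulationParams",
    "genotype_probs",
    "population_prevalence",
    "prevalence",
    "calibrate_gamma0",
    "simulate_case_control",
    "simulate_population",
    "GH_ORDER",
]

#: default Gauss-Hermite order; error << 1e-10 at the parameter scales used here
GH_ORDER = 64

_BRACKET_LIMIT = 50.0  # logit-scale search bound for gamma0 calibration


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the generative model plus sampling quotas.

    Exactly one of ``gamma0`` / ``target_rate`` must be given: an explicit
    disease-model intercept, or a population disease rate that the intercept
    is calibrated to.
    """

    beta0: float
    beta1: float
    sigma2: float
    gamma1: float
    gamma2: float
    maf: float
    n_cases: int = 500
    n_controls: int = 500
    gamma0: float | None = None
    target_rate: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ParameterError(f"sigma2 must be > 0, got {self.sigma2}")
        if not 0 < self.maf <= 0.5:
            raise ParameterError(f"maf must be in (0, 0.5], got {self.maf}")
        if (self.gamma0 is None) == (self.target_rate is None):
            raise ParameterError("exactly one of gamma0 / target_rate must be set")
        if self.target_rate is not None and not 0 < self.target_rate < 1:
            raise ParameterError(f"target_rate must be in (0, 1), got {self.target_rate}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ParameterError("sampling quotas must be positive")

    def with_gamma0(self, gamma0: float) -> "SimulationParams":
        return replace(self, gamma0=gamma0, target_rate=None)


def genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities over allele counts (0, 1, 2)."""
    if not 0 < maf <= 0.5:
        raise ParameterError(f"maf must be in (0, 0.5], got {maf}")
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


@lru_cache(maxsize=None)
def _gh_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order < 2:
        raise ConfigurationError(f"quadrature order must be >= 2, got {order}")
    nodes, weights = np.polynomial.hermite.hermgauss(order)
    return nodes, weights / np.sqrt(np.pi)


def prevalence(
    gamma0: float,
    gamma1: float,
    gamma2: float,
    beta0: float,
    beta1: float,
    sigma2: float,
    level_values: np.ndarray,
    level_probs: np.ndarray,
    order: int = GH_ORDER,
) -> float:
    """P(D=1) for an arbitrary finite genotype distribution.

    Computes ``sum_x p_x * E[expit(gamma0 + gamma1*x + gamma2*Y) | X=x]``
    with the inner expectation over ``Y ~ N(beta0 + beta1*x, sigma2)``
    evaluated by Gauss-Hermite quadrature.
    """
    nodes, weights = _gh_nodes(order)
    v = np.asarray(level_values, dtype=float)[:, None]
    y = beta0 + beta1 * v + np.sqrt(2.0 * sigma2) * nodes[None, :]
    per_level = expit(gamma0 + gamma1 * v + gamma2 * y) @ weights
    return float(np.asarray(level_probs, dtype=float) @ per_level)


def population_prevalence(params: SimulationParams, order: int = GH_ORDER) -> float:
    """Population disease probability implied by fully specified parameters."""
    if params.gamma0 is None:
        raise ParameterError("gamma0 must be explicit; calibrate it first")
    return prevalence(
        params.gamma0,
        params.gamma1,
        params.gamma2,
        params.beta0,
        params.beta1,
        params.sigma2,
        np.array([0.0, 1.0, 2.0]),
        genotype_probs(params.maf),
        order=order,
    )


def calibrate_gamma0(
    params: SimulationParams,
    target_rate: float | None = None,
    order: int = GH_ORDER,
    tol: float = 1e-10,
) -> float:
    """Solve for the ``gamma0`` giving the target population disease rate.

    The prevalence is strictly increasing in ``gamma0``, so the root is
    unique; it is bracketed by expansion and solved with Brent's method to
    ``|prevalence - target| < 1e-8``.
    """
    target = params.target_rate if target_rate is None else target_rate
    if target is None or not 0 < target < 1:
        raise ParameterError(f"target rate must be in (0, 1), got {target}")

    def f(g0: float) -> float:
        return (
            prevalence(
                g0, params.gamma1, params.gamma2, params.beta0, params.beta1,
                params.sigma2, np.array([0.0, 1.0, 2.0]), genotype_probs(params.maf),
                order=order,
            )
            - target
        )

    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2.0
        if lo < -_BRACKET_LIMIT:
            raise CalibrationError("gamma0 bracket exceeded -50 on the logit scale")
    while f(hi) < 0:
        hi *= 2.0
        if hi > _BRACKET_LIMIT:
            raise CalibrationError("gamma0 bracket exceeded +50 on the logit scale")
    return float(brentq(f, lo, hi, xtol=tol))


def _resolved_gamma0(params: SimulationParams, order: int = GH_ORDER) -> float:
    if params.gamma0 is not None:
        return params.gamma0
    return calibrate_gamma0(params, order=order)


def simulate_population(
    params: SimulationParams,
    n: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` unascertained individuals; returns ``(x, y, d)`` arrays."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    gamma0 = _resolved_gamma0(params)
    probs = genotype_probs(params.maf)
    x = rng.choice(3, size=n, p=probs)
    y = params.beta0 + params.beta1 * x + np.sqrt(params.sigma2) * rng.standard_normal(n)
    p = expit(gamma0 + params.gamma1 * x + params.gamma2 * y)
    d = (rng.random(n) < p).astype(int)
    return x, y, d


def simulate_case_control(
    params: SimulationParams,
    block_size: int = 100_000,
    max_draws: int = 10**8,
) -> CaseControlDataset:
    """Sample a case-control dataset by quota ascertainment.

    Population individuals are drawn in vectorized blocks and retained until
    both the case and control quotas are filled; overflow of an already
    filled class is discarded, which is distributionally identical to
    sampling cases and controls as independent streams.
    """
    rng = np.random.default_rng(params.seed)
    gamma0 = _resolved_gamma0(params)
    fixed = params.with_gamma0(gamma0)

    need_case, need_ctrl = params.n_cases, params.n_controls
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    ds: list[np.ndarray] = []
    drawn = 0
    while need_case > 0 or need_ctrl > 0:
        if drawn >= max_draws:
            raise FeasibilityError(
                f"{drawn} draws without filling quotas (cases short {need_case}, "
                f"controls short {need_ctrl}); revise gamma0/target_rate"
            )
        x, y, d = simulate_population(fixed, block_size, rng=rng)
        drawn += block_size
        case_idx = np.flatnonzero(d == 1)[:need_case]
        ctrl_idx = np.flatnonzero(d == 0)[:need_ctrl]
        keep = np.sort(np.concatenate([case_idx, ctrl_idx]))
        xs.append(x[keep])
        ys.append(y[keep])
        ds.append(d[keep])
        need_case -= case_idx.size
        need_ctrl -= ctrl_idx.size

    x = np.concatenate(xs)
    # drop allele-count levels with zero occupancy (rare at these sample sizes)
    level_values, codes = np.unique(x.astype(float), return_inverse=True)
    return CaseControlDataset(
        d=np.concatenate(ds),
        y=np.concatenate(ys),
        x=codes,
        level_values=level_values,
    )
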