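"""Type-I-error / power simulation-study harness.

Runs a grid of simulation settings (genotype-on-disease effect ``gamma1``,
population disease rate, trait effect ``beta1``), simulating ``n_reps``
case-control datasets per cell and recording each requested method's
rejection rate at the chosen significance threshold, with Wilson binomial
confidence intervals and convergence counts.

Seeding: every replicate draws its generator from
``numpy.random.SeedSequence([master_seed, cell_index, replicate_index])``,
so cells are disjoint, independently re-runnable, and the whole study is
reproducible from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import assoc_tests, linzeng
from .errors import CalibrationError, ParameterError
from .simulate import SimulationParams, calibrate_gamma0, simulate_case_control

__all__ = ["StudyGrid", "StudyResult", "CellResult", "run_study",
           "binomial_ci", "power_comparison_report", "replicate_seed"]

_ALL_METHODS = (
    "proposed", "case_only", "control_only", "combined", "combined_adj",
    "linzeng_wald", "linzeng_lrt",
)


@dataclass(frozen=True)
class StudyGrid:
    """Parameter grid and protocol for a power/type-I-error study."""

    base_params: SimulationParams
    gamma1_values: tuple[float, ...] = tuple(
        np.log(r) for r in (1.0, 1.1, 1.2, 1.3, 1.4, 1.5)
    )
    disease_rates: tuple[float, ...] = (0.01, 0.05)
    beta1_values: tuple[float, ...] = (0.0, -0.12)
    n_reps: int = 1000
    alpha: float = 0.01
    methods: tuple[str, ...] = ("proposed", "case_only", "control_only", "combined")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if not (self.gamma1_values and self.disease_rates and self.beta1_values):
            raise ParameterError("grids must be non-empty")
        unknown = [m for m in self.methods if m not in _ALL_METHODS]
        if unknown:
            raise ParameterError(f"unknown methods: {unknown}")

    def cells(self):
        """Enumerate (cell_index, gamma1, rate, beta1)."""
        i = 0
        for rate in self.disease_rates:
            for beta1 in self.beta1_values:
                for gamma1 in self.gamma1_values:
                    yield i, gamma1, rate, beta1
                    i += 1


@dataclass
class CellResult:
    gamma1: float
    disease_rate: float
    beta1: float
    method: str
    n_reps: int
    n_converged: int
    n_rejected: int
    mean_statistic: float
    gamma0: float
    failed: bool = False

    @property
    def rejection_rate(self) -> float:
        return self.n_rejected / self.n_converged if self.n_converged else float("nan")

    @property
    def ci(self) -> tuple[float, float]:
        if not self.n_converged:
            return (float("nan"), float("nan"))
        return binomial_ci(self.n_rejected, self.n_converged)


@dataclass
class StudyResult:
    grid: StudyGrid
    cells: list[CellResult] = field(default_factory=list)

    def lookup(self, gamma1: float, rate: float, beta1: float, method: str) -> CellResult:
        for c in self.cells:
            if (
                abs(c.gamma1 - gamma1) < 1e-12
                and c.disease_rate == rate
                and c.beta1 == beta1
                and c.method == method
            ):
                return c
        raise KeyError((gamma1, rate, beta1, method))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            lo, hi = c.ci
            rows.append(
                {
                    "gamma1": c.gamma1, "disease_rate": c.disease_rate,
                    "beta1": c.beta1, "method": c.method, "n_reps": c.n_reps,
                    "n_converged": c.n_converged, "rejection_rate": c.rejection_rate,
                    "ci_low": lo, "ci_high": hi,
                    "mean_statistic": c.mean_statistic, "gamma0": c.gamma0,
                    "failed": c.failed,
                }
            )
        return pd.DataFrame(rows)


def replicate_seed(master_seed: int, cell_index: int, rep_index: int) -> np.random.SeedSequence:
    """Deterministic, cross-cell-disjoint seed for one replicate."""
    return np.random.SeedSequence([master_seed, cell_index, rep_index])


def binomial_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ParameterError(f"invalid counts ({successes}, {trials})")
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method="wilson")
    # guard against floating-point dust at the boundaries: the interval must
    # sit inside [0, 1] and contain the point estimate
    phat = successes / trials
    lo = min(max(float(lo), 0.0), phat)
    hi = max(min(float(hi), 1.0), phat)
    return lo, hi


def _apply_method(method: str, dataset):
    if method == "linzeng_wald":
        return linzeng.wald_test_beta1(linzeng.fit_retrospective(dataset))
    if method == "linzeng_lrt":
        return linzeng.lrt_beta1(dataset)
    return assoc_tests.METHODS[method](dataset)


def run_study(grid: StudyGrid, progress: bool = False) -> StudyResult:
    """Execute the study grid; one :class:`CellResult` per (cell, method).

    Rejection rates are computed among converged replicates only, with the
    convergence count reported alongside — retrospective-likelihood fits
    may legitimately fail under the null and that must stay visible.
    A cell whose intercept calibration fails is marked failed and the study
    continues.
    """
    out = StudyResult(grid=grid)
    for cell_idx, gamma1, rate, beta1 in grid.cells():
        base = replace(
            grid.base_params, gamma1=gamma1, beta1=beta1,
            gamma0=None, target_rate=rate,
        )
        try:
            gamma0 = calibrate_gamma0(base)
        except CalibrationError:
            for m in grid.methods:
                out.cells.append(
                    CellResult(gamma1, rate, beta1, m, grid.n_reps, 0, 0,
                               float("nan"), float("nan"), failed=True)
                )
            continue
        params = base.with_gamma0(gamma0)
        tallies = {m: [0, 0, 0.0] for m in grid.methods}  # converged, rejected, stat sum
        for rep in range(grid.n_reps):
            seed = replicate_seed(grid.seed, cell_idx, rep)
            ds = simulate_case_control(replace(params, seed=seed))
            for m in grid.methods:
                res = _apply_method(m, ds)
                if res.converged and np.isfinite(res.p_value):
                    tallies[m][0] += 1
                    tallies[m][1] += res.p_value < grid.alpha
                    tallies[m][2] += res.statistic
            if progress and (rep + 1) % 100 == 0:
                print(f"cell {cell_idx}: {rep + 1}/{grid.n_reps}", flush=True)
        for m in grid.methods:
            n_conv, n_rej, stat_sum = tallies[m]
            out.cells.append(
                CellResult(
                    gamma1, rate, beta1, m, grid.n_reps, n_conv, int(n_rej),
                    stat_sum / n_conv if n_conv else float("nan"), gamma0,
                )
            )
    return out


def power_comparison_report(result: StudyResult, path, plot_path=None) -> None:
    """Write the per-cell TSV and, optionally, rejection-rate line plots.

    The plot facets by disease rate and trait-effect size, drawing one
    rejection-rate-vs-gamma1 line per method.  Reporting only: no numeric
    claims are asserted here.
    """
    if not result.cells:
        raise ValueError("empty StudyResult")
    frame = result.to_frame()
    for col in ("rejection_rate", "ci_low", "ci_high", "mean_statistic", "gamma0"):
        frame[col] = frame[col].map(lambda x: float(f"{x:.6g}"))
    frame.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        _plot(frame, result.grid, plot_path)


def _plot(frame: pd.DataFrame, grid: StudyGrid, plot_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rates = sorted(frame["disease_rate"].unique())
    betas = sorted(frame["beta1"].unique())
    fig, axes = plt.subplots(
        len(betas), len(rates), squeeze=False,
        figsize=(5 * len(rates), 4 * len(betas)), sharey="row",
    )
    for i, beta1 in enumerate(betas):
        for j, rate in enumerate(rates):
            ax = axes[i][j]
            sub = frame[(frame["beta1"] == beta1) & (frame["disease_rate"] == rate)]
            for m, g in sub.groupby("method"):
                g = g.sort_values("gamma1")
                ax.plot(np.exp(g["gamma1"]), g["rejection_rate"], marker="o", label=m)
            ax.axhline(grid.alpha, color="grey", ls=":")
            ax.set_xlabel("odds ratio exp(gamma1)")
            ax.set_ylabel("rejection rate")
            ax.set_title(f"disease rate {rate:g}, beta1 {beta1:g}")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
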