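"""Association tests for a secondary phenotype in a case-control sample.

``proposed_lrt`` is the screening test of the two-step workflow: it compares
cumulative-logit models of the ordinal genotype given disease status with and
without the secondary phenotype, yielding a 1-df chi-squared likelihood-ratio
statistic.  Because both models condition on disease status, the test is
valid under case-control ascertainment without modelling the sampling.

The comparator tests (``case_only_test``, ``control_only_test``,
``combined_test``) are the naive linear regressions of phenotype on additive
genotype code that the method is benchmarked against; the combined test
optionally conditions on disease status.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .data_io import CaseControlDataset, TestResult
from .errors import DataError, DegenerateGenotypeError, DesignError
from .ordinal import fit_cumulative_logit

__all__ = [
    "proposed_lrt",
    "case_only_test",
    "control_only_test",
    "combined_test",
    "run_batch",
    "METHODS",
]


def proposed_lrt(dataset: CaseControlDataset, adjust: Sequence[str] = ()) -> TestResult:
    """Proportional-odds likelihood-ratio test of genotype-phenotype association.

    Null model: ``logit P(X <= j | .) = alpha_j + delta_D * D (+ covariates)``.
    Alternative adds ``delta_Y * Y``.  The statistic is twice the
    log-likelihood difference (clamped at zero against optimizer tolerance),
    referred to chi-squared with 1 df: only the ``Y`` coefficient is tested,
    regardless of how many confounders are adjusted for.

    Covariates named in ``adjust`` enter BOTH models.
    """
    if np.unique(dataset.x).shape[0] < 2:
        raise DegenerateGenotypeError("fewer than 2 occupied genotype levels")
    if dataset.n_cases == 0 or dataset.n_controls == 0:
        raise DataError("both cases and controls are required")
    cov = dataset.covariate_matrix(adjust)
    z_null = np.column_stack([dataset.d.astype(float), cov])
    z_alt = np.column_stack([dataset.y, dataset.d.astype(float), cov])

    fit_null = fit_cumulative_logit(dataset.x, z_null)
    fit_alt = fit_cumulative_logit(dataset.x, z_alt)
    if not (fit_null.converged and fit_alt.converged):
        notes = "; ".join(
            f"{lbl}: {f.notes or 'non-converged'}"
            for lbl, f in (("null", fit_null), ("alt", fit_alt))
            if not f.converged
        )
        return TestResult(
            method="proposed",
            statistic=float("nan"),
            df=1,
            p_value=float("nan"),
            n_used=dataset.n,
            converged=False,
            notes=notes,
        )
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    notes = ""
    if stat < 0:
        notes = f"negative LRT {stat:.2e} clamped to 0 (optimizer tolerance)"
        stat = 0.0
    return TestResult(
        method="proposed",
        statistic=stat,
        df=1,
        p_value=float(stats.chi2.sf(stat, df=1)),
        n_used=dataset.n,
        notes=notes,
    )


def _ols_slope_test(y: np.ndarray, g: np.ndarray, extra: np.ndarray, method: str) -> TestResult:
    """Squared-t test of the genotype slope in an OLS fit of y on [1, g, extra]."""
    n = y.shape[0]
    if np.ptp(g) == 0:
        raise DegenerateGenotypeError(f"{method}: genotype constant in analysis stratum")
    X = np.column_stack([np.ones(n), g, extra])
    k = X.shape[1]
    if n <= k:
        raise DesignError(f"{method}: too few subjects ({n}) for {k} parameters")
    if np.linalg.matrix_rank(X) < k:
        raise DesignError(f"{method}: rank-deficient design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - k
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        # perfect fit: infinite t; report a machine-floor p-value
        return TestResult(
            method=method,
            statistic=float("inf"),
            df=1,
            p_value=np.nextafter(0, 1),
            n_used=n,
            converged=False,
            notes="zero residual variance; p below machine floor",
        )
    s2 = rss / df_resid
    se = np.sqrt(s2 * xtx_inv[1, 1])
    t = beta[1] / se
    return TestResult(
        method=method,
        statistic=float(t * t),
        df=1,
        p_value=float(2.0 * stats.t.sf(abs(t), df_resid)),
        n_used=n,
    )


def case_only_test(dataset: CaseControlDataset, adjust: Sequence[str] = ()) -> TestResult:
    """OLS of Y on additive genotype code among cases only."""
    sub = dataset.subset(dataset.d == 1)
    return _ols_slope_test(sub.y, sub.x.astype(float), sub.covariate_matrix(adjust), "case_only")


def control_only_test(dataset: CaseControlDataset, adjust: Sequence[str] = ()) -> TestResult:
    """OLS of Y on additive genotype code among controls only."""
    sub = dataset.subset(dataset.d == 0)
    return _ols_slope_test(sub.y, sub.x.astype(float), sub.covariate_matrix(adjust), "control_only")


def combined_test(
    dataset: CaseControlDataset,
    adjust: Sequence[str] = (),
    condition_on_d: bool = False,
) -> TestResult:
    """OLS of Y on genotype over all subjects; optionally adjusts for D."""
    if dataset.n_cases == 0 or dataset.n_controls == 0:
        raise DataError("both strata must be non-empty")
    extra = dataset.covariate_matrix(adjust)
    if condition_on_d:
        extra = np.column_stack([dataset.d.astype(float), extra])
    method = "combined_adj" if condition_on_d else "combined"
    return _ols_slope_test(dataset.y, dataset.x.astype(float), extra, method)


#: method name -> callable(dataset, adjust) for batch screening and the study harness
METHODS = {
    "proposed": proposed_lrt,
    "case_only": case_only_test,
    "control_only": control_only_test,
    "combined": combined_test,
    "combined_adj": lambda ds, adjust=(): combined_test(ds, adjust, condition_on_d=True),
}


def run_batch(
    table,
    snp_ids: Sequence[str],
    genotype_matrix: np.ndarray,
    methods: Sequence[str] = ("proposed",),
    adjust: Sequence[str] = (),
    mode: str = "counts",
) -> list[tuple[str, TestResult]]:
    """Apply the requested tests to each SNP of a genotype matrix.

    ``table`` is a :class:`~secophen.data_io.PhenotypeTable`; rows of
    ``genotype_matrix`` correspond to ``snp_ids``.  SNPs that are
    monomorphic or otherwise untestable yield a non-converged result row
    rather than aborting the batch.
    """
    from .data_io import attach_genotypes

    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise DesignError(f"unknown methods: {unknown}")
    out: list[tuple[str, TestResult]] = []
    for snp_id, row in zip(snp_ids, genotype_matrix):
        try:
            ds = attach_genotypes(table, row, mode=mode)
        except DegenerateGenotypeError as exc:
            for m in methods:
                out.append(
                    (snp_id, TestResult(m, float("nan"), 1, float("nan"), 0, False, str(exc)))
                )
            continue
        for m in methods:
            try:
                out.append((snp_id, METHODS[m](ds, adjust)))
            except (DegenerateGenotypeError, DesignError) as exc:
                out.append(
                    (snp_id, TestResult(m, float("nan"), 1, float("nan"), ds.n, False, str(exc)))
                )
    return out
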