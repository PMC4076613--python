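"""Subject-level data model and readers/writers.

The central container is :class:`CaseControlDataset`: disease status ``d``
(0/1), a quantitative secondary phenotype ``y``, an ordinal genotype code
``x`` in ``0..J`` with the raw values the codes stand for in
``level_values``, and optional real covariates.  Construction validates the
invariants once so downstream model code can assume clean input.

Readers perform row-wise complete-case filtering and report how many
subjects were dropped; subject order is always preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateGenotypeError,
    SiteLookupError,
    UnsupportedSiteError,
)

__all__ = [
    "PhenotypeTable",
    "CaseControlDataset",
    "TestResult",
    "read_phenotype_table",
    "attach_genotypes",
    "read_vcf_genotypes",
    "read_genotype_matrix",
    "write_results_table",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class PhenotypeTable:
    """Parsed phenotype table before genotypes are attached.

    Attributes
    ----------
    d, y : ndarray
        Disease indicator (0/1 ints) and secondary phenotype, subject order
        as in the input file after complete-case filtering.
    covariates : ndarray or None
        ``(n, p)`` real covariate matrix, or ``None``.
    covariate_names : tuple of str
    n_dropped : int
        Rows removed because a mapped field was missing.
    """

    d: np.ndarray
    y: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: tuple[str, ...] = ()
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class CaseControlDataset:
    """Complete subject-level dataset: disease, phenotype, ordinal genotype.

    Invariants (checked at construction): equal lengths, ``d`` binary,
    ``x`` integer codes in ``0..J`` with every level occupied implied by
    the attach step, ``level_values`` strictly increasing with ``J + 1``
    entries, no missing values.
    """

    d: np.ndarray
    y: np.ndarray
    x: np.ndarray
    level_values: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: tuple[str, ...] = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=int)
        y = np.asarray(self.y, dtype=float)
        x = np.asarray(self.x, dtype=int)
        lv = np.asarray(self.level_values, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "level_values", lv)
        n = d.shape[0]
        if y.shape[0] != n or x.shape[0] != n:
            raise DataError("d, y, x must have equal length")
        if not np.isin(d, (0, 1)).all():
            raise DataError("disease status must be 0/1")
        if not (np.isfinite(y).all() and np.isfinite(lv).all()):
            raise DataError("missing or non-finite values after construction")
        if lv.ndim != 1 or lv.shape[0] < 2 or np.any(np.diff(lv) <= 0):
            raise DataError("level_values must be strictly increasing with >= 2 entries")
        if x.min(initial=0) < 0 or x.max(initial=0) > lv.shape[0] - 1:
            raise DataError("genotype codes outside 0..J")
        if self.covariates is not None:
            cov = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if cov.shape[0] != n:
                raise DataError("covariate rows must match subject count")
            if not np.isfinite(cov).all():
                raise DataError("missing covariate values after construction")
            object.__setattr__(self, "covariates", cov)

    @property
    def n(self) -> int:
        return self.d.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.d.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @property
    def n_levels(self) -> int:
        return self.level_values.shape[0]

    @property
    def j_max(self) -> int:
        """J: highest genotype code (number of levels minus one)."""
        return self.n_levels - 1

    @property
    def x_values(self) -> np.ndarray:
        """Raw genotype values per subject (``level_values[x]``)."""
        return self.level_values[self.x]

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Columns of the covariate matrix selected by name."""
        if not names:
            return np.empty((self.n, 0))
        if self.covariates is None:
            raise ConfigurationError(f"dataset has no covariates; requested {list(names)}")
        missing = [c for c in names if c not in self.covariate_names]
        if missing:
            raise ConfigurationError(f"unknown covariates: {missing}")
        idx = [self.covariate_names.index(c) for c in names]
        return self.covariates[:, idx]

    def subset(self, mask: np.ndarray) -> "CaseControlDataset":
        """Row subset (does not re-index genotype levels)."""
        return CaseControlDataset(
            d=self.d[mask],
            y=self.y[mask],
            x=self.x[mask],
            level_values=self.level_values,
            covariates=None if self.covariates is None else self.covariates[mask],
            covariate_names=self.covariate_names,
            n_dropped=self.n_dropped,
        )


@dataclass
class TestResult:
    """Outcome of one association test on one SNP."""

    __test__ = False  # not a pytest class, despite the name

    method: str
    statistic: float
    df: int
    p_value: float
    n_used: int
    converged: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if not np.isfinite(self.statistic):
                raise ValueError("converged result must have a finite statistic")
            if not (0.0 <= self.p_value <= 1.0):
                raise ValueError("p_value outside [0, 1]")


def read_phenotype_table(
    path,
    column_map: Mapping[str, str],
    delimiter: str = "\t",
) -> PhenotypeTable:
    """Read a delimited phenotype table.

    ``column_map`` maps roles to column names: keys ``"d"`` and ``"y"`` are
    required; ``"covariates"`` may give a list of covariate column names.
    Rows with any missing mapped field are dropped and counted.
    """
    if "d" not in column_map or "y" not in column_map:
        raise ConfigurationError("column_map must name 'd' and 'y' columns")
    table = pd.read_csv(path, sep=delimiter)
    cov_names = list(column_map.get("covariates", []))
    wanted = [column_map["d"], column_map["y"], *cov_names]
    missing = [c for c in wanted if c not in table.columns]
    if missing:
        raise ConfigurationError(f"missing column(s) in {path}: {missing}")

    sub = table[wanted].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    sub = sub[keep]

    d_raw = sub[column_map["d"]].to_numpy(dtype=float)
    bad = ~np.isin(d_raw, (0.0, 1.0))
    if bad.any():
        row = sub.index[np.flatnonzero(bad)[0]]
        raise DataError(
            f"non-binary disease status {d_raw[np.flatnonzero(bad)[0]]!r} at input row {row + 2}"
        )
    covariates = sub[cov_names].to_numpy(dtype=float) if cov_names else None
    return PhenotypeTable(
        d=d_raw.astype(int),
        y=sub[column_map["y"]].to_numpy(dtype=float),
        covariates=covariates,
        covariate_names=tuple(cov_names),
        n_dropped=n_dropped,
    )


def attach_genotypes(
    table: PhenotypeTable,
    genotypes: np.ndarray,
    mode: str = "counts",
    max_levels: int = 21,
) -> CaseControlDataset:
    """Attach raw genotype values to a phenotype table, producing ordinal codes.

    ``counts`` mode expects allele counts in {0, 1, 2}; codes are the counts
    and ``level_values`` the occupied counts.  ``dosage`` mode turns the
    distinct observed values into ordered levels; if there are more than
    ``max_levels`` distinct values they are first snapped to ``max_levels``
    equally spaced grid points on ``[min, max]`` (nearest point, ties to the
    lower level).  Subjects with a missing genotype are dropped (complete-case
    per SNP) and added to ``n_dropped``.  Levels left empty are removed and
    codes re-indexed contiguously.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.shape[0] != table.n:
        raise DataError(f"genotype vector length {g.shape[0]} != subject count {table.n}")
    present = np.isfinite(g)
    n_missing = int((~present).sum())
    g = g[present]

    if mode == "counts":
        if not np.isin(g, (0.0, 1.0, 2.0)).all():
            raise DataError("counts mode requires genotype values in {0, 1, 2}")
    elif mode == "dosage":
        if np.unique(g).shape[0] > max_levels:
            lo, hi = g.min(), g.max()
            grid = np.linspace(lo, hi, max_levels)
            # nearest grid point, ties resolved to the lower level
            up = np.searchsorted(grid, g, side="left").clip(1, max_levels - 1)
            lo_idx = up - 1
            pick_hi = (grid[up] - g) < (g - grid[lo_idx])
            g = grid[np.where(pick_hi, up, lo_idx)]
    else:
        raise ConfigurationError(f"unknown genotype mode {mode!r}")

    level_values, codes = np.unique(g, return_inverse=True)
    if level_values.shape[0] < 2:
        raise DegenerateGenotypeError(
            f"monomorphic genotype ({level_values.shape[0]} occupied level); no test possible"
        )
    return CaseControlDataset(
        d=table.d[present],
        y=table.y[present],
        x=codes,
        level_values=level_values,
        covariates=None if table.covariates is None else table.covariates[present],
        covariate_names=table.covariate_names,
        n_dropped=table.n_dropped + n_missing,
    )


def read_vcf_genotypes(
    path,
    site_selector: Mapping[str, object] | str,
    field: str = "GT",
    sample_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Extract one site's genotypes from a VCF as raw values.

    ``site_selector`` is either a variant ID string or a mapping with
    ``chrom`` and ``pos``.  ``field`` ``"GT"`` returns ALT-allele counts
    0/1/2 (missing -> NaN; biallelic sites only); ``"DS"`` returns the
    dosage FORMAT value.  Output follows ``sample_order`` when given,
    otherwise VCF header order.
    """
    from cyvcf2 import VCF

    if field not in ("GT", "DS"):
        raise ConfigurationError(f"field must be 'GT' or 'DS', got {field!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_order is not None:
        absent = [s for s in sample_order if s not in samples]
        if absent:
            raise ConfigurationError(f"samples missing from VCF header: {absent}")

    if isinstance(site_selector, str):
        match = lambda v: v.ID == site_selector  # noqa: E731
        desc = f"ID={site_selector}"
    else:
        chrom = str(site_selector["chrom"])
        pos = int(site_selector["pos"])
        match = lambda v: v.CHROM == chrom and v.POS == pos  # noqa: E731
        desc = f"{chrom}:{pos}"

    for variant in vcf:
        if not match(variant):
            continue
        if field == "GT":
            if len(variant.ALT) != 1:
                raise UnsupportedSiteError(f"site {desc} is not biallelic (GT mode)")
            # variant.genotypes: [allele0, allele1, phased] per sample; -1 = missing
            values = np.array(
                [
                    np.nan if min(g[:-1]) < 0 else float(sum(a > 0 for a in g[:-1]))
                    for g in variant.genotypes
                ],
                dtype=float,
            )
        else:
            ds = variant.format("DS")
            if ds is None:
                raise ConfigurationError(f"site {desc} has no DS FORMAT field")
            values = np.asarray(ds, dtype=float).reshape(-1)
            values = np.where(values < 0, np.nan, values)
        if sample_order is not None:
            idx = [samples.index(s) for s in sample_order]
            values = values[idx]
        return values
    raise SiteLookupError(f"site {desc} not found in {path}")


def read_genotype_matrix(path, orientation: str = "snps_by_subjects", delimiter: str = "\t"):
    """Read a delimited genotype matrix.

    Returns ``(snp_ids, matrix)`` with ``matrix`` of shape
    ``(n_snps, n_subjects)``.  The first column holds SNP identifiers
    (``snps_by_subjects``) or the header holds them (``subjects_by_snps``).
    """
    table = pd.read_csv(path, sep=delimiter, index_col=0)
    if orientation == "subjects_by_snps":
        table = table.T
    elif orientation != "snps_by_subjects":
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    return list(table.index.astype(str)), table.to_numpy(dtype=float)


_RESULT_COLUMNS = ("snp_id", "method", "statistic", "df", "p_value", "n_used", "converged", "notes")


def write_results_table(results: Sequence[tuple[str, TestResult]], path) -> None:
    """Write per-SNP test results as TSV, floats at 6 significant digits."""
    if not results:
        raise ValueError("results must be non-empty")
    rows = []
    for snp_id, r in results:
        rows.append(
            {
                "snp_id": snp_id,
                "method": r.method,
                "statistic": f"{r.statistic:.6g}",
                "df": r.df,
                "p_value": f"{r.p_value:.6g}",
                "n_used": r.n_used,
                "converged": r.converged,
                "notes": r.notes,
            }
        )
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_dataset(dataset: CaseControlDataset, prefix) -> tuple[str, str]:
    """Write a dataset as a phenotype TSV + genotype matrix TSV pair."""
    pheno_path = f"{prefix}.pheno.tsv"
    geno_path = f"{prefix}.geno.tsv"
    cols = {"d": dataset.d, "y": dataset.y}
    for j, name in enumerate(dataset.covariate_names):
        cols[name] = dataset.covariates[:, j]
    pd.DataFrame(cols).to_csv(pheno_path, sep="\t", index=False)
    geno = pd.DataFrame(
        [dataset.x_values], index=pd.Index(["snp1"], name="snp_id"),
        columns=[f"s{i}" for i in range(dataset.n)],
    )
    geno.to_csv(geno_path, sep="\t")
    return pheno_path, geno_path


def read_dataset(pheno_path, geno_path, covariates: Sequence[str] = (),
                 mode: str = "counts", snp_id: str | None = None) -> CaseControlDataset:
    """Read the phenotype + genotype matrix pair written by :func:`write_dataset`."""
    table = read_phenotype_table(
        pheno_path, {"d": "d", "y": "y", "covariates": list(covariates)}
    )
    snp_ids, geno = read_genotype_matrix(geno_path)
    row = 0 if snp_id is None else snp_ids.index(snp_id)
    return attach_genotypes(table, geno[row], mode=mode)
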