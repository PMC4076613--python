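"""Readers/writers: parsing rules, VCF extraction, round trips."""

import numpy as np
import pandas as pd
import pytest

from secophen.assoc_tests import proposed_lrt
from secophen.data_io import (
    CaseControlDataset,
    PhenotypeTable,
    TestResult,
    attach_genotypes,
    read_dataset,
    read_genotype_matrix,
    read_phenotype_table,
    read_vcf_genotypes,
    write_dataset,
    write_results_table,
)
from secophen.errors import (
    ConfigurationError,
    DataError,
    DegenerateGenotypeError,
    SiteLookupError,
    UnsupportedSiteError,
)

CMAP = {"d": "d", "y": "y"}


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadPhenotypeTable:
    def test_basic_parse(self, tmp_path):
        p = write_tsv(tmp_path / "p.tsv", "d\ty\n1\t0.2\n1\t-1.1\n0\t0.4\n0\t0.9\n")
        t = read_phenotype_table(p, CMAP)
        assert t.n == 4
        assert t.d.sum() == 2
        np.testing.assert_allclose(t.y, [0.2, -1.1, 0.4, 0.9])
        assert t.n_dropped == 0

    def test_missing_y_row_dropped(self, tmp_path):
        p = write_tsv(tmp_path / "p.tsv", "d\ty\n1\t0.2\n1\t\n0\t0.4\n")
        t = read_phenotype_table(p, CMAP)
        assert t.n == 2
        assert t.n_dropped == 1

    def test_nonbinary_d_rejected_with_row(self, tmp_path):
        p = write_tsv(tmp_path / "p.tsv", "d\ty\n1\t0.2\n2\t0.3\n")
        with pytest.raises(DataError, match="row 3"):
            read_phenotype_table(p, CMAP)

    def test_missing_column_named(self, tmp_path):
        p = write_tsv(tmp_path / "p.tsv", "status\ty\n1\t0.2\n")
        with pytest.raises(ConfigurationError, match="d"):
            read_phenotype_table(p, CMAP)

    def test_covariates(self, tmp_path):
        p = write_tsv(tmp_path / "p.tsv", "d\ty\tage\n1\t0.2\t50\n0\t0.1\t61\n")
        t = read_phenotype_table(p, {"d": "d", "y": "y", "covariates": ["age"]})
        assert t.covariate_names == ("age",)
        np.testing.assert_allclose(t.covariates[:, 0], [50.0, 61.0])


def ptable(n=5, d=None, y=None):
    return PhenotypeTable(
        d=np.asarray(d if d is not None else [1, 1, 0, 0, 0]),
        y=np.asarray(y if y is not None else [0.1, 0.2, 0.3, 0.4, 0.5]),
    )


class TestAttachGenotypes:
    def test_counts(self):
        ds = attach_genotypes(ptable(), np.array([0, 1, 2, 1, 0]), mode="counts")
        np.testing.assert_array_equal(ds.x, [0, 1, 2, 1, 0])
        np.testing.assert_array_equal(ds.level_values, [0, 1, 2])
        assert ds.j_max == 2

    def test_dosage_distinct_values(self):
        t = PhenotypeTable(d=np.array([1, 0, 0, 1]), y=np.arange(4.0))
        ds = attach_genotypes(t, np.array([0.0, 0.0, 1.0, 2.0]), mode="dosage")
        assert ds.j_max == 2
        np.testing.assert_array_equal(ds.x, [0, 0, 1, 2])

    def test_monomorphic_error(self):
        with pytest.raises(DegenerateGenotypeError):
            attach_genotypes(ptable(), np.ones(5), mode="counts")

    def test_missing_genotype_dropped_and_counted(self):
        g = np.array([0.0, 1.0, np.nan, 2.0, 1.0])
        ds = attach_genotypes(ptable(), g, mode="counts")
        assert ds.n == 4
        assert ds.n_dropped == 1

    def test_counts_out_of_domain(self):
        with pytest.raises(DataError):
            attach_genotypes(ptable(), np.array([0, 1, 3, 1, 0]), mode="counts")

    def test_dosage_quantization(self):
        t = PhenotypeTable(d=np.tile([0, 1], 25), y=np.arange(50.0))
        g = np.round(np.linspace(0, 2, 50), 3)
        ds = attach_genotypes(t, g, mode="dosage", max_levels=5)
        assert ds.n_levels <= 5
        # grid points on [0, 2] with 5 levels
        assert set(np.round(ds.level_values, 6)) <= {0.0, 0.5, 1.0, 1.5, 2.0}

    def test_idempotent_on_counts(self):
        ds = attach_genotypes(ptable(), np.array([0, 1, 2, 1, 0]), mode="counts")
        ds2 = attach_genotypes(ptable(), ds.x_values, mode="counts")
        np.testing.assert_array_equal(ds.x, ds2.x)
        np.testing.assert_array_equal(ds.level_values, ds2.level_values)

    def test_empty_level_reindexed(self):
        t = PhenotypeTable(d=np.array([1, 0, 1, 0]), y=np.arange(4.0))
        ds = attach_genotypes(t, np.array([0, 0, 2, 2]), mode="counts")
        assert ds.n_levels == 2
        np.testing.assert_array_equal(ds.x, [0, 0, 1, 1])


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT:DS\t0/1:1.46\t1|1:1.97\t./.:0.5\t0/0:0.02
1\t200\trs2\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\t0/0\t0/0
"""


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "test.vcf"
    p.write_text(VCF_TEXT)
    return p


class TestReadVcf:
    def test_gt_counts(self, vcf_path):
        g = read_vcf_genotypes(vcf_path, "rs1", field="GT")
        np.testing.assert_array_equal(g[:2], [1.0, 2.0])
        assert np.isnan(g[2])
        assert g[3] == 0.0

    def test_ds_passthrough(self, vcf_path):
        g = read_vcf_genotypes(vcf_path, "rs1", field="DS")
        np.testing.assert_allclose(g, [1.46, 1.97, 0.5, 0.02], atol=1e-6)

    def test_site_by_position(self, vcf_path):
        g = read_vcf_genotypes(vcf_path, {"chrom": "1", "pos": 100}, field="GT")
        assert g[1] == 2.0

    def test_missing_site(self, vcf_path):
        with pytest.raises(SiteLookupError):
            read_vcf_genotypes(vcf_path, "rs999", field="GT")

    def test_multiallelic_gt_rejected(self, vcf_path):
        with pytest.raises(UnsupportedSiteError):
            read_vcf_genotypes(vcf_path, "rs2", field="GT")

    def test_sample_order(self, vcf_path):
        g = read_vcf_genotypes(vcf_path, "rs1", field="GT", sample_order=["S2", "S1"])
        np.testing.assert_array_equal(g, [2.0, 1.0])

    def test_absent_sample(self, vcf_path):
        with pytest.raises(ConfigurationError, match="S9"):
            read_vcf_genotypes(vcf_path, "rs1", field="GT", sample_order=["S1", "S9"])


class TestResultsTable:
    def res(self, stat=4.2345678, p=0.039512345):
        return TestResult("proposed", stat, 1, p, 1000)

    def test_single_row(self, tmp_path):
        out = tmp_path / "r.tsv"
        write_results_table([("rs1", self.res())], out)
        lines = out.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].split("\t")[:3] == ["snp_id", "method", "statistic"]

    def test_three_snps_two_methods(self, tmp_path):
        out = tmp_path / "r.tsv"
        rows = [(f"rs{i}", self.res()) for i in range(3) for _ in range(2)]
        write_results_table(rows, out)
        assert len(out.read_text().strip().split("\n")) == 7

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results_table([], tmp_path / "r.tsv")

    def test_round_trip_6_sig_digits(self, tmp_path):
        out = tmp_path / "r.tsv"
        write_results_table([("rs1", self.res(stat=12.3456789, p=0.000423456789))], out)
        back = pd.read_csv(out, sep="\t")
        assert back.loc[0, "statistic"] == pytest.approx(12.3456789, rel=1e-5)
        assert back.loc[0, "p_value"] == pytest.approx(0.000423456789, rel=1e-5)


class TestDatasetRoundTrip:
    def test_write_read(self, tmp_path, null_dataset):
        prefix = tmp_path / "sim"
        write_dataset(null_dataset, prefix)
        back = read_dataset(f"{prefix}.pheno.tsv", f"{prefix}.geno.tsv")
        np.testing.assert_array_equal(back.d, null_dataset.d)
        np.testing.assert_array_equal(back.x, null_dataset.x)
        np.testing.assert_allclose(back.y, null_dataset.y, atol=1e-12)

    def test_genotype_matrix_orientations(self, tmp_path):
        p = tmp_path / "g.tsv"
        pd.DataFrame(
            [[0, 1, 2], [1, 1, 0]],
            index=pd.Index(["rs1", "rs2"], name="snp_id"),
            columns=["s1", "s2", "s3"],
        ).to_csv(p, sep="\t")
        ids, m = read_genotype_matrix(p)
        assert ids == ["rs1", "rs2"]
        assert m.shape == (2, 3)
        ids_t, m_t = read_genotype_matrix(p, orientation="subjects_by_snps")
        assert m_t.shape == (3, 2)


class TestPermutationInvariance:
    def test_shuffled_subjects_same_statistic(self, null_dataset):
        base = proposed_lrt(null_dataset)
        rng = np.random.default_rng(0)
        perm = rng.permutation(null_dataset.n)
        shuffled = CaseControlDataset(
            d=null_dataset.d[perm],
            y=null_dataset.y[perm],
            x=null_dataset.x[perm],
            level_values=null_dataset.level_values,
        )
        assert proposed_lrt(shuffled).statistic == pytest.approx(
            base.statistic, abs=1e-6
        )


class TestDatasetInvariants:
    def test_length_mismatch(self):
        with pytest.raises(DataError):
            CaseControlDataset(
                d=np.array([0, 1]), y=np.array([0.1]), x=np.array([0, 1]),
                level_values=np.array([0.0, 1.0]),
            )

    def test_nonbinary_d(self):
        with pytest.raises(DataError):
            CaseControlDataset(
                d=np.array([0, 2]), y=np.array([0.1, 0.2]), x=np.array([0, 1]),
                level_values=np.array([0.0, 1.0]),
            )

    def test_levels_must_increase(self):
        with pytest.raises(DataError):
            CaseControlDataset(
                d=np.array([0, 1]), y=np.array([0.1, 0.2]), x=np.array([0, 1]),
                level_values=np.array([1.0, 0.0]),
            )
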