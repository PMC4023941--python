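"""Table I/O, dosage orientation, and complete-case filtering."""

import numpy as np
import pandas as pd
import pytest

import dopagrs as d
from dopagrs.cohort import CohortError


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


def test_genotype_table_roundtrip(tmp_path, hs5, sim_cohort):
    path = tmp_path / "geno.tsv"
    d.write_genotype_table(sim_cohort, path)
    back = d.read_genotype_table(path, hs5)
    pd.testing.assert_frame_equal(back.genotypes, sim_cohort.genotypes)


def test_genotype_parsing_and_missing(tmp_path, hs5):
    path = _write(tmp_path / "g.tsv",
                  "subject_id\trs4680\nS1\tG/A\nS2\t./.\nS3\tMet/Val\n")
    cohort = d.read_genotype_table(path, hs5)
    assert cohort.genotypes.loc["S1", "rs4680"] == "A/G"   # order-normalized
    assert pd.isna(cohort.genotypes.loc["S2", "rs4680"])
    assert cohort.genotypes.loc["S3", "rs4680"] == "A/G"   # aliases resolved


def test_duplicate_subjects_rejected(tmp_path, hs5):
    path = _write(tmp_path / "g.tsv", "subject_id\trs4680\nS1\tA/A\nS1\tG/G\n")
    with pytest.raises(CohortError, match="duplicate"):
        d.read_genotype_table(path, hs5)


def test_malformed_genotype_rejected(tmp_path, hs5):
    path = _write(tmp_path / "g.tsv", "subject_id\trs4680\nS1\tA/T\n")
    with pytest.raises(d.PanelError):
        d.read_genotype_table(path, hs5)


def test_unknown_variant_column_kept_but_ignored(tmp_path, hs5, caplog):
    path = _write(tmp_path / "g.tsv", "subject_id\trs4680\trs9999\nS1\tA/A\tC/C\n")
    with caplog.at_level("INFO"):
        cohort = d.read_genotype_table(path, hs5)
    assert "rs9999" in cohort.genotypes.columns
    assert "ignored by scoring" in caplog.text
    # scoring a panel without rs9999 still works
    scores = d.compute_grs_hardcall(cohort, d.subset_panel(hs5, ["rs4680"]))
    assert scores.loc["S1", "score"] == 2


def test_dosage_orientation_flip(tmp_path, hs5):
    """A column counting the non-risk allele is flipped d -> 2 - d at read time."""
    path = _write(tmp_path / "d.tsv", "subject_id\trs4680\nS1\t1.37\n")
    oriented = d.read_dosage_table(path, hs5, {"rs4680": "Met"})
    assert oriented.dosages.loc["S1", "rs4680"] == pytest.approx(1.37)
    flipped = d.read_dosage_table(path, hs5, {"rs4680": "Val"})
    assert flipped.dosages.loc["S1", "rs4680"] == pytest.approx(0.63)
    assert flipped.dosage_alleles["rs4680"] == "A"
    # flip applied twice is the identity
    assert 2 - (2 - 1.37) == pytest.approx(1.37)


def test_dosage_bounds_and_metadata(tmp_path, hs5):
    path = _write(tmp_path / "d.tsv", "subject_id\trs4680\nS1\t2.3\n")
    with pytest.raises(CohortError, match="outside"):
        d.read_dosage_table(path, hs5, {"rs4680": "A"})
    ok = _write(tmp_path / "d2.tsv", "subject_id\trs4680\nS1\t1.0\n")
    with pytest.raises(CohortError, match="metadata"):
        d.read_dosage_table(ok, hs5, {})


def test_dosage_roundtrip(tmp_path, hs5, sim_cohort):
    path = tmp_path / "dose.tsv"
    meta = tmp_path / "meta.tsv"
    d.write_dosage_table(sim_cohort, path, meta)
    back = d.read_dosage_table(path, hs5, str(meta))
    pd.testing.assert_frame_equal(back.dosages, sim_cohort.dosages)
    assert back.dosage_alleles == sim_cohort.dosage_alleles


def test_phenotype_scale_bounds(tmp_path):
    path = _write(tmp_path / "p.tsv", "subject_id\tcesd\tage\nS1\t61\t20\n")
    with pytest.raises(CohortError, match="range"):
        d.read_phenotype_table(path, "cesd", scale="cesd")
    ok = d.read_phenotype_table(path, "cesd")  # undeclared scale: not enforced
    assert ok.phenotype.loc["S1"] == 61
    assert list(ok.covariates.columns) == ["age"]


def test_vcf_biallelic_read(tmp_path, hs5):
    vcf_text = """##fileformat=VCFv4.2
##contig=<ID=22>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
22\t19951271\trs4680\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/1\t./.
"""
    path = _write(tmp_path / "t.vcf", vcf_text)
    panel = d.subset_panel(hs5, ["rs4680"])
    cohort = d.read_vcf_biallelic(path, panel)
    assert cohort.genotypes.loc["S1", "rs4680"] == "A/A"
    assert cohort.genotypes.loc["S2", "rs4680"] == "A/G"
    assert pd.isna(cohort.genotypes.loc["S3", "rs4680"])


def test_vcf_missing_panel_snp(tmp_path, hs5):
    vcf_text = """##fileformat=VCFv4.2
##contig=<ID=22>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
22\t1\trs9999\tG\tA\t.\tPASS\t.\tGT\t0/0
"""
    path = _write(tmp_path / "t.vcf", vcf_text)
    with pytest.raises(CohortError, match="absent"):
        d.read_vcf_biallelic(path, d.subset_panel(hs5, ["rs4680"]))


def _cohort_with_missing(n, n_missing, variant="rs4680"):
    idx = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
    geno = pd.Series(["A/G"] * n, index=idx)
    geno.iloc[:n_missing] = np.nan
    return d.CohortTable(genotypes=pd.DataFrame({variant: geno}))


@pytest.mark.parametrize("n,n_missing,expected", [(1267, 126, 9.94), (442, 61, 13.8)])
def test_exclusion_percentages(n, n_missing, expected):
    cohort = _cohort_with_missing(n, n_missing)
    kept, report = d.complete_case_filter(cohort, ["rs4680"])
    assert report.n_retained == n - n_missing
    assert report.percent_excluded == pytest.approx(expected, abs=0.005)


def test_filter_stages_and_idempotence(hs5):
    idx = pd.Index([f"S{i}" for i in range(10)], name="subject_id")
    geno = pd.DataFrame({"rs4680": ["A/G"] * 10}, index=idx)
    geno.iloc[0:2, 0] = np.nan
    pheno = pd.Series([5.0] * 10, index=idx)
    pheno.iloc[2] = np.nan
    cohort = d.CohortTable(genotypes=geno, phenotype=pheno)
    kept, report = d.complete_case_filter(cohort, ["rs4680", "phenotype"])
    assert report.stage_excluded == {"variants": 2, "phenotype_covariates": 1}
    assert report.n_retained == 7
    again, report2 = d.complete_case_filter(kept, ["rs4680", "phenotype"])
    assert report2.n_excluded == 0 and report2.percent_excluded == 0.0
    pd.testing.assert_frame_equal(again.genotypes, kept.genotypes)


def test_filter_empty_result_names_worst_field():
    cohort = _cohort_with_missing(5, 5)
    with pytest.raises(CohortError, match="rs4680"):
        d.complete_case_filter(cohort, ["rs4680"])


def test_filter_unknown_field():
    cohort = _cohort_with_missing(5, 0)
    with pytest.raises(CohortError, match="not present"):
        d.complete_case_filter(cohort, ["rs9999"])


def test_join_intersects_subjects(sim_cohort):
    geno_only = d.CohortTable(genotypes=sim_cohort.genotypes.iloc[:100])
    pheno_only = d.CohortTable(phenotype=sim_cohort.phenotype.iloc[50:])
    joined = geno_only.join(pheno_only)
    assert joined.n == 50
    assert joined.genotypes is not None and joined.phenotype is not None
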