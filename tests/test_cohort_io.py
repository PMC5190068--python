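import numpy as np
import pandas as pd
import pytest

from recursig.cohort import (
    ClinicalRecord,
    CohortError,
    attach_clinical,
    filter_eligible_samples,
    read_clinical_table,
    read_expression_matrix,
    write_clinical_table,
    write_expression_matrix,
    zscore_normalize,
)
from .conftest import make_cohort


def _write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadExpressionMatrix:
    def test_parses_genes_and_samples(self, tmp_path):
        p = _write(tmp_path, "gene\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        c = read_expression_matrix(p, "toy")
        assert c.genes == ["g1", "g2", "g3"]
        assert c.samples == ["s1", "s2"]
        assert c.values.loc["g2", "s2"] == 4.0

    def test_duplicate_gene_keeps_max_variance_row(self, tmp_path):
        # g1 rows with variance 0.5 and 2.0: the spread-out one is kept
        p = _write(tmp_path, "gene\ts1\ts2\ns0\t0\t0\ng1\t1\t2\ng1\t1\t3\n")
        c = read_expression_matrix(p, "toy")
        assert c.genes.count("g1") == 1
        assert list(c.values.loc["g1"]) == [1.0, 3.0]

    def test_empty_file_is_header_error(self, tmp_path):
        with pytest.raises(CohortError, match="no header"):
            read_expression_matrix(_write(tmp_path, ""), "toy")

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        p = _write(tmp_path, "gene\ts1\ts2\ng1\t1\tx\n")
        with pytest.raises(CohortError, match="g1.*s2"):
            read_expression_matrix(p, "toy")

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = _write(tmp_path, "gene\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(CohortError, match="duplicate sample"):
            read_expression_matrix(p, "toy")


class TestClinicalTable:
    def test_days_parsed_as_number(self, tmp_path):
        p = _write(tmp_path,
                   "sample_id\trecurrence_status\tdays_to_tumor_recurrence\n"
                   "s1\trecurrence\t453\n")
        (rec,) = read_clinical_table(p)
        assert rec.days_to_tumor_recurrence == 453.0

    def test_blank_recurrence_maps_to_unknown(self, tmp_path):
        p = _write(tmp_path, "sample_id\trecurrence_status\nsA\t\n")
        (rec,) = read_clinical_table(p)
        assert rec.recurrence_status == "unknown"

    def test_negative_days_rejected(self, tmp_path):
        p = _write(tmp_path,
                   "sample_id\trecurrence_status\tdays_to_tumor_recurrence\n"
                   "s1\trecurrence\t-5\n")
        with pytest.raises(CohortError, match=">= 0"):
            read_clinical_table(p)

    def test_unrecognized_columns_preserved_as_covariates(self, tmp_path):
        p = _write(tmp_path, "sample_id\tca125_class\ns1\thigh\n")
        (rec,) = read_clinical_table(p)
        assert rec.covariates == {"ca125_class": "high"}

    def test_recurrence_without_days_violates_invariant(self):
        with pytest.raises(CohortError):
            ClinicalRecord(sample_id="x", recurrence_status="recurrence")


def _five_sample_cohort():
    c = make_cohort({"g1": [1.0, 2.0, 3.0, 4.0, 5.0]},
                    ["recurrence"] * 5, normalized=False)
    clin = c.clinical
    clin["s0"].debulking = "suboptimal"
    clin["s1"].days_to_tumor_recurrence = 60.0
    return c


class TestEligibilityFilter:
    def test_three_rules_on_toy_table(self):
        kept = filter_eligible_samples(_five_sample_cohort())
        assert kept.samples == ["s2", "s3", "s4"]

    def test_identity_when_all_eligible(self):
        c = make_cohort({"g1": [1.0, 2.0]}, ["recurrence", "norecurrence"],
                        normalized=False)
        assert filter_eligible_samples(c).samples == c.samples

    def test_idempotent(self):
        once = filter_eligible_samples(_five_sample_cohort())
        twice = filter_eligible_samples(once)
        assert twice.samples == once.samples

    def test_exact_threshold_day_excluded(self):
        c = make_cohort({"g1": [1.0, 2.0]}, ["recurrence", "recurrence"],
                        normalized=False)
        c.clinical["s0"].days_to_tumor_recurrence = 90.0
        assert filter_eligible_samples(c).samples == ["s1"]

    def test_threshold_zero_keeps_status_rules_only(self):
        c = _five_sample_cohort()
        kept = filter_eligible_samples(c, min_recurrence_days=0)
        assert kept.samples == ["s1", "s2", "s3", "s4"]

    def test_all_removed_is_error(self):
        c = make_cohort({"g1": [1.0]}, ["recurrence"], normalized=False)
        c.clinical["s0"].debulking = "suboptimal"
        with pytest.raises(CohortError, match="empty cohort"):
            filter_eligible_samples(c)


class TestZscoreNormalize:
    def test_simple_row(self):
        c = make_cohort({"g1": [1.0, 2.0, 3.0]}, ["recurrence"] * 3,
                        normalized=False)
        z = zscore_normalize(c)
        assert np.allclose(z.values.loc["g1"], [-1, 0, 1])
        assert z.normalized

    def test_constant_row_zeroed_and_flagged(self):
        c = make_cohort({"g1": [5.0, 5.0, 5.0], "g2": [1.0, 2.0, 3.0]},
                        ["recurrence"] * 3, normalized=False)
        z = zscore_normalize(c)
        assert np.allclose(z.values.loc["g1"], 0)
        assert z.zero_variance_genes == ("g1",)

    def test_idempotent_within_tolerance(self):
        c = make_cohort({"g1": [1.0, 2.0, 4.0, 8.0]}, ["recurrence"] * 4,
                        normalized=False)
        z1 = zscore_normalize(c)
        z2 = zscore_normalize(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-9)

    def test_row_means_and_sds(self, rng):
        c = make_cohort({f"g{i}": list(rng.normal(i, i + 1, 20)) for i in range(5)},
                        ["recurrence"] * 20, normalized=False)
        z = zscore_normalize(c)
        assert np.allclose(z.values.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_preserves_sample_rank_order_per_gene(self, rng):
        vals = {f"g{i}": list(rng.normal(0, 3, 15)) for i in range(4)}
        c = make_cohort(vals, ["recurrence"] * 15, normalized=False)
        z = zscore_normalize(c)
        for g in c.genes:
            assert (np.argsort(c.values.loc[g]) == np.argsort(z.values.loc[g])).all()

    def test_single_sample_error(self):
        c = make_cohort({"g1": [1.0]}, ["recurrence"], normalized=False)
        with pytest.raises(CohortError):
            zscore_normalize(c)


def test_expression_round_trip(tmp_path, rng):
    vals = {f"g{i}": list(rng.normal(0, 2, 6)) for i in range(3)}
    c = make_cohort(vals, ["recurrence"] * 6, normalized=False)
    path = tmp_path / "roundtrip.tsv"
    write_expression_matrix(c, path)
    back = read_expression_matrix(path, "toy")
    assert np.allclose(back.values, c.values, atol=1e-9)
    assert back.genes == c.genes and back.samples == c.samples


def test_clinical_round_trip(tmp_path):
    c = _five_sample_cohort()
    path = tmp_path / "clin.tsv"
    write_clinical_table(c.clinical.values(), path)
    back = read_clinical_table(path)
    assert [r.sample_id for r in back] == c.samples
    assert back[0].debulking == "suboptimal"
    assert back[1].days_to_tumor_recurrence == 60.0
    assert back[0].covariates["days_to_last_followup"] == "300.0"


def test_attach_clinical_restricts_to_shared_samples():
    c = make_cohort({"g1": [1.0, 2.0, 3.0]}, ["recurrence"] * 3, normalized=False)
    records = [c.clinical["s0"], c.clinical["s2"]]
    attached = attach_clinical(
        type(c)(name="t", values=c.values), records
    )
    assert attached.samples == ["s0", "s2"]
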