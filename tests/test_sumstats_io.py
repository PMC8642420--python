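import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetmr import sumstats_io
from targetmr.exceptions import FormatError, HarmonizationError, ValidationError
from targetmr.types import AssociationRecord, CorrelationMatrix, MREstimate

from conftest import make_record

SIX_SNPS = ["rs12916", "rs10066707", "rs17238484", "rs2006760", "rs2303152", "rs5909"]


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)


class TestReadSumstats:
    def test_six_rows_in_file_order(self, tmp_path):
        lines = ["snp_id\teffect_allele\tother_allele\tbeta\tse\teaf\tpval"]
        for i, snp in enumerate(SIX_SNPS):
            lines.append(f"{snp}\tA\tG\t{0.07 - 0.01 * i}\t0.005\t0.4\t1e-20")
        path = _write(tmp_path / "exp.tsv", "\n".join(lines) + "\n")
        records = sumstats_io.read_sumstats(path)
        assert [r.snp_id for r in records] == SIX_SNPS
        assert records[0].beta == pytest.approx(0.07)
        assert all(r.scale == "sd" for r in records)

    def test_csv_with_aliases(self, tmp_path):
        path = _write(
            tmp_path / "exp.csv",
            "SNP,A1,A2,b,standard_error,freq,p\nrs1,A,G,0.1,0.02,0.25,1e-8\n",
        )
        (rec,) = sumstats_io.read_sumstats(path)
        assert rec.snp_id == "rs1"
        assert rec.effect_allele == "A"
        assert rec.other_allele == "G"
        assert rec.beta == 0.1
        assert rec.se == 0.02
        assert rec.eaf == 0.25
        assert rec.pval == 1e-8

    def test_missing_mandatory_column_named(self, tmp_path):
        path = _write(tmp_path / "x.tsv", "snp_id\tbeta\tse\nrs1\t0.1\t0.01\n")
        with pytest.raises(FormatError, match="effect_allele"):
            sumstats_io.read_sumstats(path)

    def test_se_zero_is_row_level_error(self, tmp_path):
        path = _write(
            tmp_path / "x.tsv",
            "snp_id\teffect_allele\tother_allele\tbeta\tse\nrs1\tA\tG\t0.1\t0\n",
        )
        with pytest.raises(ValidationError, match="rs1"):
            sumstats_io.read_sumstats(path)

    def test_nonfinite_beta_lists_rows(self, tmp_path):
        path = _write(
            tmp_path / "x.tsv",
            "snp_id\teffect_allele\tother_allele\tbeta\tse\n"
            "rs1\tA\tG\t0.1\t0.01\nrs2\tA\tG\tnan\t0.01\n",
        )
        with pytest.raises(FormatError, match=r"\[1\]"):
            sumstats_io.read_sumstats(path)

    def test_duplicate_snp_error(self, tmp_path):
        path = _write(
            tmp_path / "x.tsv",
            "snp_id\teffect_allele\tother_allele\tbeta\tse\n"
            "rs1\tA\tG\t0.1\t0.01\nrs1\tA\tG\t0.2\t0.01\n",
        )
        with pytest.raises(FormatError, match="rs1"):
            sumstats_io.read_sumstats(path)


@st.composite
def association_records(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    records = []
    for i in range(n):
        ea, oa = draw(
            st.sampled_from([("A", "G"), ("T", "C"), ("A", "C"), ("G", "T")])
        )
        records.append(
            AssociationRecord(
                snp_id=f"rs{i + 1}",
                effect_allele=ea,
                other_allele=oa,
                beta=draw(
                    st.floats(-2, 2, allow_nan=False, allow_infinity=False)
                ),
                se=draw(st.floats(1e-6, 1.0)),
                eaf=draw(st.one_of(st.none(), st.floats(1e-3, 1 - 1e-3))),
                pval=draw(st.one_of(st.none(), st.floats(1e-300, 1.0, exclude_min=False))),
                n=draw(st.one_of(st.none(), st.integers(1, 10**7))),
                scale="sd",
            ).validate()
        )
    return records


class TestRoundTrip:
    @settings(max_examples=25, deadline=None)
    @given(records=association_records())
    def test_write_then_read_is_identity(self, records, tmp_path_factory):
        path = str(tmp_path_factory.mktemp("rt") / "s.tsv")
        sumstats_io.write_sumstats(records, path)
        back = sumstats_io.read_sumstats(path, scale="sd")
        assert back == records


class TestCorrelationMatrixIO:
    def test_identity_round_trip(self, tmp_path):
        path = _write(tmp_path / "ld.tsv", "snp_id\trs1\trs2\nrs1\t1\t0\nrs2\t0\t1\n")
        corr = sumstats_io.read_correlation_matrix(path)
        assert corr.snp_ids == ["rs1", "rs2"]
        np.testing.assert_array_equal(corr.r, np.eye(2))

    def test_high_symmetric_r_accepted(self, tmp_path):
        path = _write(
            tmp_path / "ld.tsv", "snp_id\trs1\trs2\nrs1\t1\t0.95\nrs2\t0.95\t1\n"
        )
        corr = sumstats_io.read_correlation_matrix(path)
        assert corr.r[0, 1] == pytest.approx(0.95)
        np.testing.assert_allclose(corr.r, corr.r.T)

    def test_out_of_range_r_rejected(self, tmp_path):
        path = _write(
            tmp_path / "ld.tsv", "snp_id\trs1\trs2\nrs1\t1\t2.0\nrs2\t2.0\t1\n"
        )
        with pytest.raises(FormatError, match="r"):
            sumstats_io.read_correlation_matrix(path)

    def test_asymmetry_rejected(self, tmp_path):
        path = _write(
            tmp_path / "ld.tsv", "snp_id\trs1\trs2\nrs1\t1\t0.5\nrs2\t0.3\t1\n"
        )
        with pytest.raises(FormatError, match="asymmetry"):
            sumstats_io.read_correlation_matrix(path)

    def test_rsid_mismatch_rejected(self, tmp_path):
        path = _write(
            tmp_path / "ld.tsv", "snp_id\trs1\trs2\nrs1\t1\t0\nrsX\t0\t1\n"
        )
        with pytest.raises(FormatError, match="mismatch"):
            sumstats_io.read_correlation_matrix(path)

    def test_write_read_round_trip_of_decayed_block(self, tmp_path):
        from targetmr.synthetic_data import make_ld_block

        corr = make_ld_block(5, 0.9)
        path = str(tmp_path / "ld.tsv")
        sumstats_io.write_correlation_matrix(corr, path)
        back = sumstats_io.read_correlation_matrix(path)
        assert back.snp_ids == corr.snp_ids
        np.testing.assert_allclose(back.r, corr.r, atol=1e-12)

    def test_psd_repair_of_rounded_singular_matrix(self, tmp_path):
        # rank-deficient but valid matrix, rounded to 4 decimals: the tiny
        # negative eigenvalue introduced by rounding must be repaired away
        r = np.array([[1.0, 0.6, 0.6], [0.6, 1.0, 1.0], [0.6, 1.0, 1.0]])
        rounded = np.round(r + 1e-5 * np.array([[0, 1, -1], [1, 0, 0], [-1, 0, 0]]), 4)
        rounded = (rounded + rounded.T) / 2
        lines = ["snp_id\trs1\trs2\trs3"]
        for sid, row in zip(["rs1", "rs2", "rs3"], rounded):
            lines.append(sid + "\t" + "\t".join(f"{v:.4f}" for v in row))
        path = _write(tmp_path / "ld.tsv", "\n".join(lines) + "\n")
        corr = sumstats_io.read_correlation_matrix(path)
        assert np.linalg.eigvalsh(corr.r).min() >= -1e-12

    def test_indefinite_matrix_rejected(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(FormatError, match="positive semi-definite"):
            sumstats_io._psd_repair(r)


class TestHarmonize:
    def test_matching_alleles_copied(self):
        exp = make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.07)
        out = make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=-0.02)
        (h,) = sumstats_io.harmonize([exp], [out])
        assert h.beta_outcome == -0.02
        assert not h.flipped and not h.dropped

    def test_swapped_alleles_negated(self):
        exp = make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.07)
        out = make_record(snp_id="rs1", effect_allele="G", other_allele="A", beta=0.02)
        (h,) = sumstats_io.harmonize([exp], [out])
        assert h.beta_outcome == -0.02
        assert h.flipped

    def test_strand_complement_resolved(self):
        exp = make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.07)
        out = make_record(snp_id="rs1", effect_allele="T", other_allele="C", beta=0.02)
        (h,) = sumstats_io.harmonize([exp], [out])
        assert h.beta_outcome == 0.02
        assert not h.flipped

    def test_complement_swapped_negated(self):
        exp = make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.07)
        out = make_record(snp_id="rs1", effect_allele="C", other_allele="T", beta=0.02)
        (h,) = sumstats_io.harmonize([exp], [out])
        assert h.beta_outcome == -0.02
        assert h.flipped

    def test_unresolvable_alleles_dropped(self):
        exp = make_record(snp_id="rs1", effect_allele="A", other_allele="G")
        out = make_record(snp_id="rs1", effect_allele="A", other_allele="C")
        (h,) = sumstats_io.harmonize([exp], [out])
        assert h.dropped_reason == "allele mismatch"

    def test_empty_intersection_errors(self):
        exp = [make_record(snp_id="rs1")]
        out = [make_record(snp_id="rs2")]
        with pytest.raises(HarmonizationError, match="no shared instruments"):
            sumstats_io.harmonize(exp, out)

    # default policy: drop palindromes when either frequency is ambiguous
    # (min(eaf, 1-eaf) >= 0.42) or missing; otherwise align by frequency
    @pytest.mark.parametrize(
        "eaf_exp,eaf_out,expect",
        [
            (0.49, 0.49, "dropped"),  # both ambiguous
            (0.30, 0.45, "dropped"),  # outcome ambiguous
            (0.45, 0.30, "dropped"),  # exposure ambiguous
            (None, 0.30, "dropped"),  # missing frequency
            (0.30, 0.30, "kept"),  # same side of 0.5
            (0.30, 0.70, "flipped"),  # opposite sides
            (0.70, 0.30, "flipped"),
            (0.70, 0.70, "kept"),
        ],
    )
    def test_palindromic_policy_table(self, eaf_exp, eaf_out, expect):
        exp = make_record(
            snp_id="rs1", effect_allele="A", other_allele="T", eaf=eaf_exp, beta=0.07
        )
        out = make_record(
            snp_id="rs1", effect_allele="A", other_allele="T", eaf=eaf_out, beta=0.02
        )
        (h,) = sumstats_io.harmonize([exp], [out])
        if expect == "dropped":
            assert h.dropped_reason == "palindromic, ambiguous frequency"
        elif expect == "kept":
            assert not h.dropped and not h.flipped and h.beta_outcome == 0.02
        else:
            assert not h.dropped and h.flipped and h.beta_outcome == -0.02

    @settings(max_examples=50, deadline=None)
    @given(
        beta_out=st.floats(-1, 1, allow_nan=False),
        se_out=st.floats(1e-4, 0.5),
    )
    def test_involution_swapping_outcome_alleles(self, beta_out, se_out):
        # harmonizing against a fully allele-swapped, beta-negated outcome
        # file must give identical harmonized betas
        exp = make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.07)
        out = make_record(
            snp_id="rs1", effect_allele="A", other_allele="G", beta=beta_out, se=se_out
        )
        swapped = make_record(
            snp_id="rs1",
            effect_allele="G",
            other_allele="A",
            beta=-beta_out,
            se=se_out,
            eaf=0.7,
        )
        (h1,) = sumstats_io.harmonize([exp], [out])
        (h2,) = sumstats_io.harmonize([exp], [swapped])
        assert h1.beta_outcome == h2.beta_outcome
        assert h1.se_outcome == h2.se_outcome

    def test_flip_preserves_magnitude_and_se(self):
        exp = make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.07)
        out = make_record(
            snp_id="rs1", effect_allele="G", other_allele="A", beta=0.031, se=0.004
        )
        (h,) = sumstats_io.harmonize([exp], [out])
        assert abs(h.beta_outcome) == 0.031
        assert h.se_outcome == 0.004


class TestAlignCorrelation:
    def test_flipped_snp_negates_row_and_column(self, instrument_factory):
        r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        corr = CorrelationMatrix(["rs1", "rs2", "rs3"], r)
        insts = [
            instrument_factory(snp_id="rs1"),
            instrument_factory(snp_id="rs2", flipped=True),
            instrument_factory(snp_id="rs3"),
        ]
        aligned = sumstats_io.align_correlation(corr, insts)
        expected = r.copy()
        expected[1, :] *= -1
        expected[:, 1] *= -1
        np.testing.assert_allclose(aligned.r, expected)
        assert np.all(np.diag(aligned.r) == 1.0)

    def test_subset_respects_instrument_order(self, instrument_factory):
        r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        corr = CorrelationMatrix(["rs1", "rs2", "rs3"], r)
        insts = [instrument_factory(snp_id="rs3"), instrument_factory(snp_id="rs1")]
        aligned = sumstats_io.align_correlation(corr, insts)
        assert aligned.snp_ids == ["rs3", "rs1"]
        assert aligned.r[0, 1] == pytest.approx(0.2)


class TestWriteResults:
    def test_reported_estimate_formatting(self, tmp_path):
        # log-OR/SE reconstructed from a published OR 2.05 (1.20-3.52): the
        # OR and p round to the printed values; the symmetric CI prints
        # (1.20, 3.51) because the published interval is not exactly
        # symmetric on the log scale after rounding
        est = MREstimate.from_beta_se(
            0.71784, 0.27453, method="wald", n_snps=1, outcome="asthma", stratum="EAS_overall"
        )
        path = str(tmp_path / "res.tsv")
        sumstats_io.write_results([est], path)
        header, row = (line.split("\t") for line in open(path).read().splitlines())
        vals = dict(zip(header, row))
        assert vals["or"] == "2.05"
        assert vals["ci_low"] == "1.20"
        assert vals["ci_high"] == "3.51"
        assert vals["pval"] == "0.009"
        assert vals["q_pval"] == "NA"

    def test_empty_list_header_only(self, tmp_path):
        path = str(tmp_path / "res.tsv")
        sumstats_io.write_results([], path)
        lines = open(path).read().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("outcome\tstratum")

    def test_null_effect_symmetric_ci(self, tmp_path):
        est = MREstimate.from_beta_se(0.0, 0.1, method="wald", n_snps=1)
        path = str(tmp_path / "res.tsv")
        sumstats_io.write_results([est], path)
        header, row = (line.split("\t") for line in open(path).read().splitlines())
        vals = dict(zip(header, row))
        assert vals["or"] == "1.00"
        lo, hi = float(vals["ci_low"]), float(vals["ci_high"])
        assert lo * hi == pytest.approx(1.0, abs=0.01)  # symmetric on log scale
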