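"""Core containers, GTF/TSV I/O, FPKM normalization and filtering."""

import numpy as np
import pandas as pd
import pytest

from isodyn.core import (ExpressionMatrix, GTFParseError, ValidationError,
                         average_replicates, compute_fpkm, filter_expressed,
                         read_gtf, read_matrix, write_gtf)
from conftest import make_metadata


GTF_TEXT = """\
1\tsrc\texon\t100\t199\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
1\tsrc\texon\t300\t399\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
1\tsrc\texon\t100\t250\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
1\tsrc\texon\t500\t599\t.\t-\t.\tgene_id "G2"; transcript_id "T3";
"""


@pytest.fixture()
def gtf_path(tmp_path):
    path = tmp_path / "ann.gtf"
    path.write_text(GTF_TEXT)
    return path


class TestReadGtf:
    def test_gene_transcript_mapping(self, gtf_path):
        ann = read_gtf(gtf_path)
        assert ann.transcripts_of_gene() == {"G1": ["T1", "T2"], "G2": ["T3"]}
        assert ann.multi_isoform_genes() == ["G1"]

    def test_length_is_sum_of_exon_widths(self, gtf_path):
        ann = read_gtf(gtf_path)
        assert ann.lengths["T1"] == 200  # (100,199) + (300,399)
        assert ann.lengths["T2"] == 151
        assert ann.exons["T1"] == [(100, 199), (300, 399)]

    def test_missing_transcript_id_names_line(self, tmp_path):
        bad = tmp_path / "bad.gtf"
        bad.write_text(GTF_TEXT + '1\tsrc\texon\t1\t9\t.\t+\t.\tgene_id "G3";\n')
        with pytest.raises(GTFParseError, match="line 5"):
            read_gtf(bad)

    def test_overlapping_duplicate_exons_merged(self, tmp_path):
        path = tmp_path / "dup.gtf"
        path.write_text(
            '1\ts\texon\t100\t199\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            '1\ts\texon\t150\t249\t.\t+\t.\tgene_id "G"; transcript_id "T";\n')
        ann = read_gtf(path)
        assert ann.lengths["T"] == 150
        assert ann.exons["T"] == [(100, 249)]

    def test_roundtrip_via_writer(self, gtf_path, tmp_path):
        ann = read_gtf(gtf_path)
        out = tmp_path / "out.gtf"
        write_gtf(ann, out)
        again = read_gtf(out)
        pd.testing.assert_frame_equal(ann.frame, again.frame)
        assert ann.exons == again.exons


class TestReadMatrix:
    def test_shape_and_values(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("transcript_id\ts1\ts2\nT1\t1\t2\nT2\t0\t5\nT3\t3\t3\n")
        mat = read_matrix(path, "counts")
        assert mat.values.shape == (3, 2)
        assert mat.layer == "counts"

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("transcript_id\ts1\nT1\t-4\n")
        with pytest.raises(ValidationError, match="negative"):
            read_matrix(path, "counts")

    def test_non_integer_counts_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("transcript_id\ts1\nT1\t1.5\n")
        with pytest.raises(ValidationError, match="integer"):
            read_matrix(path, "counts")

    def test_unknown_sample_column_rejected(self, tmp_path):
        meta = make_metadata()
        path = tmp_path / "m.tsv"
        path.write_text("transcript_id\tnot_a_sample\nT1\t1\n")
        with pytest.raises(ValidationError, match="not_a_sample"):
            read_matrix(path, "counts", meta=meta)

    def test_counts_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.integers(0, 1000, (20, 4)).astype(float),
                             index=[f"T{i}" for i in range(20)],
                             columns=list("abcd"))
        mat = ExpressionMatrix(frame, "counts")
        mat.write_tsv(tmp_path / "c.tsv")
        again = read_matrix(tmp_path / "c.tsv", "counts")
        assert (again.values.to_numpy() == frame.to_numpy()).all()

    def test_fpkm_roundtrip_close(self, tmp_path):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.gamma(2, 10, (20, 4)),
                             index=[f"T{i}" for i in range(20)],
                             columns=list("abcd"))
        ExpressionMatrix(frame, "fpkm").write_tsv(tmp_path / "f.tsv")
        again = read_matrix(tmp_path / "f.tsv", "fpkm")
        np.testing.assert_allclose(again.values.to_numpy(), frame.to_numpy(),
                                   rtol=1e-9)


def _toy_annotation(lengths):
    from isodyn.core import TranscriptAnnotation
    frame = pd.DataFrame({
        "gene_id": [f"G{i}" for i in range(len(lengths))],
        "length_bp": lengths,
    }, index=[f"T{i}" for i in range(len(lengths))])
    frame.index.name = "transcript_id"
    return TranscriptAnnotation(frame)


class TestComputeFpkm:
    def test_unit_case(self):
        meta = make_metadata(breeds=("AA",), stages=("E10",), n_replicates=1,
                             library_size=1_000_000)
        ann = _toy_annotation([1000])
        counts = ExpressionMatrix(
            pd.DataFrame({"AA_E10_1": [10.0]}, index=["T0"]), "counts")
        fpkm = compute_fpkm(counts, ann, meta)
        assert fpkm.values.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        meta = make_metadata(breeds=("AA",), stages=("E10",), n_replicates=1)
        ann = _toy_annotation([500])
        counts = ExpressionMatrix(
            pd.DataFrame({"AA_E10_1": [0.0]}, index=["T0"]), "counts")
        assert compute_fpkm(counts, ann, meta).values.iloc[0, 0] == 0.0

    def test_matches_per_cell_formula_oracle(self):
        rng = np.random.default_rng(3)
        meta = make_metadata(breeds=("AA",), stages=("E10", "E14"),
                             n_replicates=3, library_size=5_000_000)
        lengths = rng.integers(200, 5000, 20)
        ann = _toy_annotation(lengths)
        frame = pd.DataFrame(rng.integers(0, 500, (20, 6)).astype(float),
                             index=ann.transcript_ids, columns=meta.sample_ids)
        fpkm = compute_fpkm(ExpressionMatrix(frame, "counts"), ann, meta)
        for i in range(20):
            for j in range(6):
                lib = meta.library_sizes.iloc[j]
                expected = frame.iloc[i, j] / ((lengths[i] / 1e3) * (lib / 1e6))
                assert fpkm.values.iloc[i, j] == pytest.approx(expected,
                                                               abs=1e-12)

    def test_linear_in_counts_and_inverse_in_library(self):
        meta = make_metadata(breeds=("AA",), stages=("E10",), n_replicates=1,
                             library_size=2_000_000)
        ann = _toy_annotation([1000])
        one = ExpressionMatrix(pd.DataFrame({"AA_E10_1": [7.0]},
                                            index=["T0"]), "counts")
        two = ExpressionMatrix(pd.DataFrame({"AA_E10_1": [14.0]},
                                            index=["T0"]), "counts")
        f1 = compute_fpkm(one, ann, meta).values.iloc[0, 0]
        f2 = compute_fpkm(two, ann, meta).values.iloc[0, 0]
        assert f2 == pytest.approx(2 * f1)
        meta_big = make_metadata(breeds=("AA",), stages=("E10",),
                                 n_replicates=1, library_size=4_000_000)
        f_half = compute_fpkm(one, ann, meta_big).values.iloc[0, 0]
        assert f_half == pytest.approx(f1 / 2)

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError):
            make_metadata(library_size=0)


class TestFilterExpressed:
    def test_strict_inequality_at_threshold(self):
        fpkm = ExpressionMatrix(pd.DataFrame(
            {"s1": [1.0, 0.0], "s2": [1.0, 1.5]}, index=["Ta", "Tb"]), "fpkm")
        transcripts, _ = filter_expressed(fpkm)
        assert transcripts == {"Tb"}

    def test_matches_bruteforce_row_scan(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.gamma(1, 1, (50, 8)),
                             index=[f"T{i:03d}" for i in range(50)],
                             columns=[f"s{j}" for j in range(8)])
        fpkm = ExpressionMatrix(frame, "fpkm")
        got, _ = filter_expressed(fpkm, threshold=1.0)
        expected = {tid for tid, row in frame.iterrows()
                    if any(v > 1.0 for v in row)}
        assert got == expected

    def test_threshold_zero_returns_nonzero_rows(self):
        frame = pd.DataFrame({"s1": [0.0, 0.2], "s2": [0.0, 0.0]},
                             index=["Ta", "Tb"])
        got, _ = filter_expressed(ExpressionMatrix(frame, "fpkm"),
                                  threshold=0.0)
        assert got == {"Tb"}


class TestAverageReplicates:
    def test_simple_means(self):
        meta = make_metadata(breeds=("AA",), stages=("E10",), n_replicates=3)
        frame = pd.DataFrame([[1.0, 2.0, 3.0]], index=["T0"],
                             columns=meta.sample_ids)
        out = average_replicates(ExpressionMatrix(frame, "fpkm"), meta)
        assert out.loc["T0", ("AA", "E10")] == pytest.approx(2.0)

    def test_single_replicate_identity(self):
        meta = make_metadata(breeds=("AA",), stages=("E10",), n_replicates=1)
        frame = pd.DataFrame([[7.0]], index=["T0"], columns=meta.sample_ids)
        out = average_replicates(ExpressionMatrix(frame, "fpkm"), meta)
        assert out.loc["T0", ("AA", "E10")] == 7.0

    def test_matches_bruteforce_group_mean(self):
        meta = make_metadata()
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(rng.gamma(2, 5, (10, 42)),
                             index=[f"T{i}" for i in range(10)],
                             columns=meta.sample_ids)
        out = average_replicates(ExpressionMatrix(frame, "fpkm"), meta)
        for breed in meta.breeds:
            for stage in meta.stages:
                cols = [c for c in frame.columns
                        if c.startswith(f"{breed}_{stage}_")]
                np.testing.assert_allclose(out[(breed, stage)],
                                           frame[cols].mean(axis=1))
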