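import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix

from srtkit import matrix_io as mio
from srtkit.synthetic import SimulationConfig, simulate_expression, write_fixture_gtf


# --------------------------------------------------------------------------
# reading / writing
# --------------------------------------------------------------------------

class TestReadWrite:
    def test_tsv_round_trip_is_bit_exact(self, tmp_path, rng):
        m = make_matrix(
            rng.random((5, 4)) * 100,
            [f"t{i}" for i in range(5)],
            [f"s{j}" for j in range(4)],
            ["a", "a", "b", "b"],
        )
        mio.write_expression_matrix(m, tmp_path / "m.tsv", tmp_path / "meta.tsv")
        back = mio.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")
        assert (back.values.to_numpy() == m.values.to_numpy()).all()
        assert list(back.sample_type[back.sample_ids]) == list(m.sample_type[m.sample_ids])
        assert list(back.transcript_ids) == list(m.transcript_ids)

    def test_mtx_triplet_with_sidecar_names(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        vals = np.array([[0.0, 2.0], [3.5, 0.0], [0.0, 0.0]])
        mmwrite(str(tmp_path / "m.mtx"), csr_matrix(vals))
        (tmp_path / "m.mtx.rows").write_text("t1\nt2\nt3\n")
        (tmp_path / "m.mtx.cols").write_text("s1\ns2\n")
        pd.DataFrame(
            {"sample_id": ["s1", "s2"], "type": ["a", "b"], "context": ["tissue", "tissue"]}
        ).to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        m = mio.read_expression_matrix(tmp_path / "m.mtx", tmp_path / "meta.tsv")
        assert m.values.shape == (3, 2)
        assert m.values.loc["t2", "s1"] == 3.5

    def test_well_formed_table_loads(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "transcript_id\ts1\ts2\nt1\t1.0\t2.0\nt2\t0\t0.5\nt3\t3\t4\n"
        )
        (tmp_path / "meta.tsv").write_text(
            "sample_id\ttype\tcontext\ns1\tliver\ttissue\ns2\ttestis\ttissue\n"
        )
        m = mio.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")
        assert len(m.transcript_ids) == 3 and len(m.sample_ids) == 2

    def test_negative_value_names_the_cell(self, tmp_path):
        (tmp_path / "m.tsv").write_text("transcript_id\ts1\nt1\t1.0\nt2\t-1.0\n")
        (tmp_path / "meta.tsv").write_text("sample_id\ttype\tcontext\ns1\tliver\ttissue\n")
        with pytest.raises(mio.MatrixValidationError, match="t2.*s1"):
            mio.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_non_numeric_value_names_the_cell(self, tmp_path):
        (tmp_path / "m.tsv").write_text("transcript_id\ts1\nt1\tNA?\n")
        (tmp_path / "meta.tsv").write_text("sample_id\ttype\tcontext\ns1\tliver\ttissue\n")
        with pytest.raises(mio.MatrixValidationError, match="t1.*s1"):
            mio.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_sample_missing_from_metadata_names_the_sample(self, tmp_path):
        (tmp_path / "m.tsv").write_text("transcript_id\ts1\ts2\nt1\t1.0\t2.0\n")
        (tmp_path / "meta.tsv").write_text("sample_id\ttype\tcontext\ns1\tliver\ttissue\n")
        with pytest.raises(mio.MatrixValidationError, match="s2"):
            mio.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")

    def test_duplicate_transcript_id_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("transcript_id\ts1\nt1\t1.0\nt1\t2.0\n")
        (tmp_path / "meta.tsv").write_text("sample_id\ttype\tcontext\ns1\tliver\ttissue\n")
        with pytest.raises(mio.MatrixValidationError, match="t1"):
            mio.read_expression_matrix(tmp_path / "m.tsv", tmp_path / "meta.tsv")


# --------------------------------------------------------------------------
# expressed-transcript filter
# --------------------------------------------------------------------------

class TestFilterExpressed:
    def test_threshold_is_strictly_greater(self):
        m = make_matrix([[0.1, 0.1], [0.2, 0.0]], ["at", "bt"], ["s1", "s2"], ["a", "b"])
        kept = mio.filter_expressed(m, tpm_threshold=0.1)
        assert list(kept.transcript_ids) == ["bt"]  # all-0.1 row removed

    def test_planted_all_zero_rows_are_removed(self, rng):
        vals = rng.random((100, 8)) + 0.2
        zero_rows = rng.choice(100, size=10, replace=False)
        vals[zero_rows] = 0.0
        m = make_matrix(vals, [f"t{i:03d}" for i in range(100)],
                        [f"s{j}" for j in range(8)], ["a"] * 4 + ["b"] * 4)
        kept = mio.filter_expressed(m)
        assert kept.values.shape[0] == 90
        expected = [f"t{i:03d}" for i in range(100) if i not in set(zero_rows)]
        assert list(kept.transcript_ids) == expected  # row order preserved

    def test_idempotent(self, rng):
        vals = rng.random((30, 6))
        m = make_matrix(vals, [f"t{i}" for i in range(30)],
                        [f"s{j}" for j in range(6)], ["a", "a", "b", "b", "c", "c"])
        once = mio.filter_expressed(m, 0.5)
        twice = mio.filter_expressed(once, 0.5)
        assert (once.values.to_numpy() == twice.values.to_numpy()).all()

    def test_per_type_report(self):
        m = make_matrix([[1.0, 0.0], [0.0, 1.0]], ["t1", "t2"], ["s1", "s2"], ["a", "b"])
        by_type = mio.expressed_transcripts_by_type(m)
        assert by_type == {"a": ["t1"], "b": ["t2"]}


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

class TestAggregateByType:
    def test_singleton_and_mean(self):
        m = make_matrix([[2.0, 4.0, 7.0]], ["t1"], ["s1", "s2", "s3"], ["a", "a", "b"])
        prof = mio.aggregate_by_type(m)
        assert prof.x.loc["t1", "a"] == 3.0  # mean of (2, 4)
        assert prof.x.loc["t1", "b"] == 7.0  # singleton

    def test_median_aggregation(self):
        m = make_matrix([[1.0, 2.0, 9.0]], ["t1"], ["s1", "s2", "s3"], ["a", "a", "a"])
        prof = mio.aggregate_by_type(m, aggregation="median")
        assert prof.x.loc["t1", "a"] == 2.0

    def test_matches_naive_loop_oracle(self, rng):
        vals = rng.random((50, 20)) * 50
        types = [f"ty{j % 4}" for j in range(20)]
        m = make_matrix(vals, [f"t{i}" for i in range(50)], [f"s{j}" for j in range(20)], types)
        prof = mio.aggregate_by_type(m)
        for i in range(50):
            for ty in sorted(set(types)):
                cols = [j for j in range(20) if types[j] == ty]
                expected = sum(vals[i, j] for j in cols) / len(cols)
                assert prof.x.iloc[i][ty] == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_sample_permutation_within_type(self, rng):
        vals = rng.random((10, 6))
        ids = [f"s{j}" for j in range(6)]
        types = ["a", "a", "a", "b", "b", "b"]
        m1 = make_matrix(vals, [f"t{i}" for i in range(10)], ids, types)
        perm = [2, 0, 1, 5, 3, 4]  # permutes within each type
        m2 = make_matrix(vals[:, perm], [f"t{i}" for i in range(10)],
                         [ids[p] for p in perm], [types[p] for p in perm])
        assert np.allclose(mio.aggregate_by_type(m1).x, mio.aggregate_by_type(m2).x)

    def test_context_filter_and_empty_selection(self, tiny_matrix):
        with pytest.raises(ValueError):
            tiny_matrix.subset_context("tumor")
        prof = mio.aggregate_by_type(tiny_matrix, context="tissue")
        assert prof.type_labels == ["liver", "testis"]


# --------------------------------------------------------------------------
# top-variable selection
# --------------------------------------------------------------------------

class TestSelectTopVariable:
    def test_constant_transcript_ranks_last(self):
        m = make_matrix([[5.0, 5.0, 5.0], [1.0, 10.0, 100.0]],
                        ["const", "var"], ["s1", "s2", "s3"], ["a", "b", "c"])
        assert mio.select_top_variable(m, 2) == ["var", "const"]

    def test_planted_high_variance_rows_occupy_the_top(self, rng):
        n = 200
        vals = np.abs(rng.normal(10, 0.01, size=(n, 12)))
        hot = rng.choice(n, size=20, replace=False)
        vals[hot] = np.abs(rng.normal(10, 0.01, size=(20, 12)))
        vals[hot, :6] *= 100  # inflate variance of 20 rows
        ids = [f"t{i:03d}" for i in range(n)]
        m = make_matrix(vals, ids, [f"s{j}" for j in range(12)], ["a"] * 6 + ["b"] * 6)
        top = mio.select_top_variable(m, 20)
        assert set(top) == {ids[i] for i in hot}

    def test_invariant_to_row_permutation_and_tie_rule(self, rng):
        vals = rng.random((15, 5))
        vals[3] = vals[7]  # exact tie: broken by id ascending
        ids = [f"t{i:02d}" for i in range(15)]
        m1 = make_matrix(vals, ids, [f"s{j}" for j in range(5)], list("abcde"))
        perm = rng.permutation(15)
        m2 = make_matrix(vals[perm], [ids[p] for p in perm],
                         [f"s{j}" for j in range(5)], list("abcde"))
        assert mio.select_top_variable(m1, 15) == mio.select_top_variable(m2, 15)

    def test_n_exceeding_count_raises(self, tiny_matrix):
        with pytest.raises(ValueError):
            mio.select_top_variable(tiny_matrix, 4)


# --------------------------------------------------------------------------
# GTF annotation and structure summary
# --------------------------------------------------------------------------

GTF_HEADER = "#!genome-build test\n"


def _gtf_line(chrom, feature, start, end, strand, tid, gid="g1"):
    return (f'{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t'
            f'gene_id "{gid}"; transcript_id "{tid}";\n')


class TestGtfAnnotation:
    def test_two_exon_transcript_length_and_count(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            GTF_HEADER
            + _gtf_line("chr1", "exon", 1, 100, "+", "ENST1")
            + _gtf_line("chr1", "exon", 201, 300, "+", "ENST1")
        )
        (a,) = mio.read_gtf_annotation(gtf)
        assert (a.exon_count, a.length, a.start, a.end) == (2, 200, 1, 300)
        assert a.status == "annotated"

    def test_single_exon_and_novel_pattern(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(_gtf_line("chr2", "exon", 50, 149, "-", "MSTRG.1.1"))
        (a,) = mio.read_gtf_annotation(gtf)
        assert a.exon_count == 1 and a.length == 100 and a.status == "novel"

    def test_exon_without_transcript_id_raises(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\ttest\texon\t1\t10\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(ValueError, match="no parent"):
            mio.read_gtf_annotation(gtf)

    def test_end_before_start_raises(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(_gtf_line("chr1", "exon", 100, 10, "+", "ENST1"))
        with pytest.raises(ValueError, match="< start"):
            mio.read_gtf_annotation(gtf)

    def test_generated_fixture_matches_generator_bookkeeping(self, tmp_path):
        ids = [f"FIX{i}" for i in range(10)]
        record = write_fixture_gtf(ids, tmp_path / "fix.gtf", seed=7)
        annots = mio.read_gtf_annotation(tmp_path / "fix.gtf")
        assert len(annots) == 10
        for a in annots:
            assert (a.exon_count, a.length) == record[a.transcript_id]


class TestStructureSummary:
    def _annot(self, tid, exons, length, status="annotated"):
        return mio.TranscriptAnnotation(tid, "g", "chr1", 1, length, "+", exons, length, status)

    def test_novel_fraction(self):
        annots = [self._annot(f"t{i}", 1, 100, s)
                  for i, s in enumerate(["annotated", "annotated", "novel", "novel"])]
        s = mio.summarize_transcript_structure(annots)
        assert s.novel_fraction == 0.5 and s.n_annotated + s.n_novel == s.n_total

    def test_median_odd_and_even(self):
        s = mio.summarize_transcript_structure(
            [self._annot(f"t{i}", 1, L) for i, L in enumerate([100, 300, 500])])
        assert s.median_length == 300
        s = mio.summarize_transcript_structure(
            [self._annot(f"t{i}", 1, L) for i, L in enumerate([100, 300, 500, 700])])
        assert s.median_length == 300  # lower of the two middle values

    def test_exon_histogram_matches_hand_tally(self):
        counts = [1, 1, 2, 3, 5, 6, 10, 11, 20, 21, 40, 2, 4, 5, 7, 15, 25, 1, 3, 9]
        annots = [self._annot(f"t{i}", c, 100 * c) for i, c in enumerate(counts)]
        s = mio.summarize_transcript_structure(annots)
        assert s.exon_count_histogram == {"1": 3, "2-5": 7, "6-10": 4, "11-20": 3, ">20": 3}
        assert s.multi_exon_fraction == 17 / 20

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mio.summarize_transcript_structure([])
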