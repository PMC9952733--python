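"""Review ingestion, matrix round-trips, fixtures and the ground-truth table."""

import numpy as np
import pytest

from ddsim.corpus_io import (
    GroundTruthTable,
    LabeledMatrix,
    aggregate_documents,
    gt_average,
    load_fixture,
    read_matrix_csv,
    read_reviews_csv,
    write_matrix_csv,
)
from ddsim.exceptions import FormatError


def _write(tmp_path, text, name="reviews.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadReviews:
    def test_roster_in_order_of_first_appearance(self, tmp_path):
        p = _write(
            tmp_path,
            "drug_name,rating,side_effects,comments\n"
            "A,4,dizzy,ok\nA,2,rash,\nB,5,,fine\n",
        )
        corpus = read_reviews_csv(p)
        assert len(corpus) == 3
        assert corpus.roster == ["A", "B"]
        assert corpus.records[0].rating == 4
        assert corpus.records[2].side_effects == ""

    def test_header_only_file_gives_empty_corpus(self, tmp_path):
        corpus = read_reviews_csv(_write(tmp_path, "drug_name,side_effects\n"))
        assert len(corpus) == 0 and corpus.roster == []

    def test_absent_optional_column_becomes_empty_string(self, tmp_path):
        corpus = read_reviews_csv(_write(tmp_path, "drug_name,comments\nA,hello\n"))
        assert corpus.records[0].side_effects == ""
        assert corpus.records[0].comments == "hello"

    def test_missing_drug_column_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="drug-name"):
            read_reviews_csv(_write(tmp_path, "name,comments\nA,x\n"))

    def test_bad_row_error_names_row_number(self, tmp_path):
        p = _write(tmp_path, "drug_name,rating\nA,5\nB,often\n")
        with pytest.raises(FormatError, match="row 3"):
            read_reviews_csv(p)

    def test_column_map_resolves_foreign_headers(self, tmp_path):
        p = _write(tmp_path, "medicine,text\nA,hello\n")
        corpus = read_reviews_csv(
            p, column_map={"drug_name": "medicine", "comments": "text"}
        )
        assert corpus.roster == ["A"]
        assert corpus.records[0].comments == "hello"


class TestAggregateDocuments:
    def test_concatenates_fields_in_corpus_order(self, three_row_corpus):
        docs = aggregate_documents(three_row_corpus, min_reviews=0)
        assert len(docs) == 2
        a = docs[0]
        assert a.drug_name == "A" and a.n_reviews == 2
        assert a.text == "dizzy tired at night rash mild rash"

    def test_review_count_cutoff_is_strict(self, three_row_corpus):
        # the case-study rule: a drug with fewer reviews than the cutoff is dropped
        assert [d.drug_name for d in aggregate_documents(three_row_corpus, min_reviews=2)] == ["A"]
        corpus = three_row_corpus
        counts = corpus.review_counts()
        assert counts == {"A": 2, "B": 1}
        assert aggregate_documents(corpus, min_reviews=3) == []

    def test_document_count_nonincreasing_in_min_reviews(self, three_row_corpus):
        sizes = [len(aggregate_documents(three_row_corpus, m)) for m in range(0, 5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_corpus_gives_empty_list(self):
        from ddsim.corpus_io import ReviewCorpus

        assert aggregate_documents(ReviewCorpus([]), min_reviews=0) == []


class TestMatrixRoundTrip:
    def test_write_read_identity(self, tmp_path):
        m = load_fixture("table2_cs")
        out = tmp_path / "m.csv"
        write_matrix_csv(m, out)
        again = read_matrix_csv(out)
        assert again.labels == m.labels
        assert again.orientation == "similarity"
        np.testing.assert_array_equal(again.values, m.values)

    def test_rank_matrix_round_trip_keeps_integers(self, tmp_path):
        m = load_fixture("table6_cs_rank")
        out = tmp_path / "r.csv"
        write_matrix_csv(m, out)
        again = read_matrix_csv(out)
        np.testing.assert_array_equal(again.values, m.values)

    def test_non_square_block_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# orientation=similarity\n,A,B,C\nA,1,0,0\nB,0,1,0\n")
        with pytest.raises(FormatError, match="square"):
            read_matrix_csv(p)

    def test_label_mismatch_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# orientation=similarity\n,A,B\nA,1,0\nC,0,1\n")
        with pytest.raises(FormatError, match="label"):
            read_matrix_csv(p)

    def test_orientation_required_somewhere(self, tmp_path):
        p = tmp_path / "bare.csv"
        p.write_text(",A,B\nA,1.0,0.5\nB,0.5,1.0\n")
        with pytest.raises(FormatError, match="orientation"):
            read_matrix_csv(p)
        assert read_matrix_csv(p, orientation="similarity").orientation == "similarity"


class TestLabeledMatrixInvariants:
    def test_similarity_diagonal_enforced(self):
        with pytest.raises(FormatError, match="diagonal"):
            LabeledMatrix(["A", "B"], [[0.9, 0.5], [0.5, 1.0]], "similarity")

    def test_rank_rows_must_be_permutations(self):
        with pytest.raises(FormatError, match="permutation"):
            LabeledMatrix(["A", "B"], [[1, 1], [1, 2]], "rank")

    def test_drop_removes_rows_and_columns(self):
        m = load_fixture("table2_cs")
        sub = m.drop(["Klonopin"])
        assert len(sub.labels) == 13 and "Klonopin" not in sub.labels
        assert sub.loc("Carbamazepine", "Oxcarbazepine") == m.loc(
            "Carbamazepine", "Oxcarbazepine"
        )


class TestFixtures:
    def test_cosine_fixture_values(self):
        m = load_fixture("table2_cs")
        assert len(m.labels) == 14
        assert m.labels[0] == "Carbamazepine"
        assert m.loc("Carbamazepine", "Oxcarbazepine") == pytest.approx(0.65)
        np.testing.assert_array_equal(np.diag(m.values), np.ones(14))

    def test_euclidean_fixture_values(self):
        m = load_fixture("table3_ed")
        assert m.orientation == "distance"
        assert m.loc("Carbamazepine", "Oxcarbazepine") == pytest.approx(0.36)
        np.testing.assert_array_equal(np.diag(m.values), np.zeros(14))

    def test_ground_truth_fixture_has_twelve_pairs(self):
        gt = load_fixture("table13_groundtruth")
        assert isinstance(gt, GroundTruthTable)
        assert len(gt) == 12

    def test_unknown_fixture_name_raises(self):
        with pytest.raises(KeyError):
            load_fixture("table99_nope")


class TestGtAverage:
    def test_skips_missing_components(self):
        # published pair with a missing pathway cell; average over the five
        # non-pathway components, NA skipped
        assert gt_average(
            {"structure": 0.42, "target": 0.65, "go_cc": 0.92, "go_mf": 0.95, "go_bp": 0.9}
        ) == pytest.approx(0.768)

    def test_pathway_not_part_of_average(self):
        # with pathway=1 present the stored average is still the mean of the
        # other five components
        assert gt_average(
            {"structure": 0.47, "target": 0.95, "go_cc": 0.85, "go_mf": 0.86, "go_bp": 0.85}
        ) == pytest.approx(0.796)

    def test_all_ones(self):
        assert gt_average(
            {k: 1.0 for k in ("structure", "target", "go_cc", "go_mf", "go_bp")}
        ) == 1.0

    def test_all_missing_is_error(self):
        with pytest.raises(FormatError):
            gt_average({k: None for k in ("structure", "target", "go_cc", "go_mf", "go_bp")})

    def test_every_fixture_row_consistent_to_three_decimals(self):
        gt = load_fixture("table13_groundtruth")
        for p in gt.pairs:
            recomputed = gt_average(
                {
                    "structure": p.structure,
                    "target": p.target,
                    "go_cc": p.go_cc,
                    "go_mf": p.go_mf,
                    "go_bp": p.go_bp,
                }
            )
            assert round(recomputed, 3) == pytest.approx(p.average, abs=5e-4)
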