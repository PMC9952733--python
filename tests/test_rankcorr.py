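"""Rank construction and second-order Pearson analyses.

The frozen expected values (0.8549, 0.9868, 0.9824, 0.9341, 0.9396,
0.1121, 0.9912) were derived by brute-force evaluation of the correlation
formula over the published 14-element ranking rows.
"""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from ddsim.corpus_io import LabeledMatrix, load_fixture
from ddsim.exceptions import UndefinedCorrelationError
from ddsim.rankcorr import (
    average_correlations,
    drug_drug_correlation,
    measure_agreement,
    pearson,
    rank_rows,
)

CARB, OXC = "Carbamazepine", "Oxcarbazepine"


@pytest.fixture(scope="module")
def printed_ranks():
    return {
        "CS": load_fixture("table6_cs_rank"),
        "ED": load_fixture("table7_ed_rank"),
        "MD": load_fixture("table8_md_rank"),
        "JC": load_fixture("table9_jc_rank"),
    }


class TestPearson:
    def test_perfect_and_reversed(self):
        x = [3, 1, 4, 1.5, 5]
        assert pearson(x, x) == pytest.approx(1.0)
        perm = np.array([1, 4, 2, 5, 3])
        assert pearson(perm, 6 - perm) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_affine_invariance(self):
        x = np.array([2.0, 5.0, 1.0, 7.0])
        y = np.array([1.0, 0.5, 2.0, 3.0])
        assert pearson(3 * x + 2, y) == pytest.approx(pearson(x, y), abs=1e-12)

    @given(
        st.lists(st.integers(0, 100), min_size=3, max_size=20),
        st.lists(st.integers(0, 100), min_size=3, max_size=20),
    )
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_scipy_oracle(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n], float), np.array(ys[:n], float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        expected = scipy.stats.pearsonr(x, y).statistic
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    @given(st.permutations(list(range(1, 11))), st.permutations(list(range(1, 11))))
    @settings(max_examples=100, deadline=None)
    def test_equals_spearman_on_permutation_rows(self, p, q):
        # rank rows are permutations of 1..n, so Pearson on them is
        # Spearman's rho of the underlying orderings
        rho = scipy.stats.spearmanr(p, q).statistic
        assert pearson(p, q) == pytest.approx(rho, abs=1e-12)

    def test_published_ranking_rows_correlation(self, printed_ranks):
        r = printed_ranks["CS"]
        assert pearson(r.row(CARB), r.row(OXC)) == pytest.approx(0.8549, abs=5e-5)


class TestRankRows:
    def test_similarity_row_orders_descending(self):
        ranks = rank_rows(load_fixture("table2_cs"))
        assert ranks.loc("Gabapentin", "Pregabalin") == 2
        assert ranks.loc("Gabapentin", "Gabapentin") == 1

    def test_distance_row_orders_ascending(self):
        ranks = rank_rows(load_fixture("table3_ed"))
        assert ranks.loc(CARB, OXC) == 2
        assert ranks.loc(CARB, CARB) == 1

    def test_diagonal_rank_is_one_for_exact_diagonals(self):
        for name in ("table2_cs", "table3_ed", "table4_md", "table5_jc"):
            ranks = rank_rows(load_fixture(name))
            np.testing.assert_array_equal(np.diag(ranks.values), np.ones(14))

    def test_rows_are_permutations(self):
        ranks = rank_rows(load_fixture("table4_md"))
        for row in ranks.values:
            assert sorted(row) == list(range(1, 15))

    def test_invariant_under_monotone_transform(self):
        sim = load_fixture("table2_cs")
        ranks = rank_rows(sim)
        # strictly increasing transform of similarity values (keeps diag at 1
        # only if applied as distance): use exponent, rank as raw values
        warped = LabeledMatrix(sim.labels, np.exp(sim.values) / np.e, "similarity")
        np.testing.assert_array_equal(rank_rows(warped).values, ranks.values)
        dist = load_fixture("table3_ed")
        warped_d = LabeledMatrix(dist.labels, dist.values**2, "distance")
        np.testing.assert_array_equal(
            rank_rows(warped_d).values, rank_rows(dist).values
        )

    def test_rejects_rank_and_correlation_orientations(self):
        with pytest.raises(ValueError):
            rank_rows(load_fixture("table6_cs_rank"))


class TestSecondOrder:
    def test_carbamazepine_oxcarbazepine_per_measure(self, printed_ranks):
        # brute-force-derived second-order correlations for one drug pair
        expected = {"CS": 0.8549, "ED": 0.9868, "MD": 0.9824, "JC": 0.9341}
        for m, want in expected.items():
            block = drug_drug_correlation(printed_ranks[m], measure=m)
            assert block.matrix.loc(CARB, OXC) == pytest.approx(want, abs=5e-5)
            assert block.matrix.loc(OXC, CARB) == pytest.approx(want, abs=5e-5)

    def test_symmetric_unit_diagonal(self, printed_ranks):
        block = drug_drug_correlation(printed_ranks["ED"], measure="ED")
        v = block.matrix.values
        np.testing.assert_allclose(v, v.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(v), 1.0)

    def test_average_of_identical_blocks_is_the_block(self, printed_ranks):
        block = drug_drug_correlation(printed_ranks["CS"], measure="CS")
        avg = average_correlations([block, block, block])
        np.testing.assert_allclose(avg.values, block.matrix.values, atol=1e-12)

    def test_average_with_exclusion_shrinks_matrix(self, printed_ranks):
        blocks = [drug_drug_correlation(printed_ranks[m], measure=m) for m in printed_ranks]
        avg = average_correlations(blocks, exclude={"Klonopin"})
        assert len(avg.labels) == 13 and "Klonopin" not in avg.labels
        assert avg.loc(CARB, OXC) == pytest.approx(0.9396, abs=5e-5)
        np.testing.assert_allclose(avg.values, avg.values.T, atol=1e-12)

    def test_exclude_unknown_label_raises(self, printed_ranks):
        blocks = [drug_drug_correlation(printed_ranks["CS"], measure="CS")]
        with pytest.raises(KeyError):
            average_correlations(blocks, exclude={"NotADrug"})


class TestAgreement:
    def test_brute_force_derived_cells(self, printed_ranks):
        table = measure_agreement(printed_ranks)
        i = table.labels.index(CARB)
        cs_ed = table.values[i, table.pair_names.index("CS&ED")]
        ed_md = table.values[i, table.pair_names.index("ED&MD")]
        assert cs_ed == pytest.approx(0.1121, abs=5e-5)
        assert ed_md == pytest.approx(0.9912, abs=5e-5)

    def test_identical_rank_matrices_agree_perfectly(self, printed_ranks):
        r = printed_ranks["CS"]
        table = measure_agreement({"CS": r, "ED": r})
        np.testing.assert_allclose(table.values, 1.0)

    def test_averages_are_means_of_cells(self, printed_ranks):
        table = measure_agreement(printed_ranks)
        col = table.per_pair_averages()
        np.testing.assert_allclose(
            list(col.values()), table.values.mean(axis=0), atol=1e-12
        )
        row = table.per_drug_averages()
        np.testing.assert_allclose(
            list(row.values()), table.values.mean(axis=1), atol=1e-12
        )
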