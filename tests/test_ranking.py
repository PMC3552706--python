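"""Gini machinery, Lorenz-curve weights and the ranking statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lorenzgini.data import DiscretizedMatrix
from lorenzgini.ranking import (ContingencyTable, alpha_weights,
                                build_contingency, class_order, delta_weights,
                                equality_polygon, gini_dataset, gini_impurity,
                                lorenz_coefficient, lorenz_curve,
                                lorenzgini_score, rank_genes, row_distance,
                                split_status, standard_gini_index,
                                weighted_gini_index)
from conftest import random_table


class TestContingency:
    def test_build_basic(self):
        t = build_contingency([0, 0, 1], ["A", "A", "B"], ["A", "B"])
        assert t.counts.tolist() == [[2, 0], [0, 1]]
        assert t.row_totals.tolist() == [2, 1] and t.d == 3

    def test_build_reproduces_reference_totals(self, table1):
        # any code/label realization of the three-range table must give
        # the same marginals
        codes, labels = [], []
        for i, row in enumerate(table1.counts):
            for j, c in enumerate(row):
                codes += [i] * c
                labels += [f"C{j + 1}"] * c
        t = build_contingency(codes, labels, ["C1", "C2", "C3"])
        assert t.row_totals.tolist() == [40, 40, 20]
        assert t.col_totals.tolist() == [10, 40, 50]
        assert t.d == 100

    def test_empty_ranges_dropped_and_single_row(self):
        t = build_contingency([0, 0, 2], ["A", "B", "B"], ["A", "B"])
        assert t.m == 2  # code 1 never observed
        t = build_contingency([0, 0, 0], ["A", "B", "B"], ["A", "B"])
        assert t.m == 1 and t.counts.tolist() == [[1, 2]]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([], [], ["A", "B"])


class TestGiniPieces:
    def test_impurity_values(self, table1):
        assert gini_impurity(table1.counts[0]) == pytest.approx(0.405,
                                                                abs=1e-12)
        assert gini_impurity([0, 0, 16]) == 0.0
        assert gini_impurity([10, 10, 10]) == pytest.approx(2 / 3, abs=1e-12)

    def test_impurity_rejects_all_zero(self):
        with pytest.raises(ValueError):
            gini_impurity([0, 0, 0])

    def test_standard_index(self, table1, table2_left):
        assert standard_gini_index(table1) == pytest.approx(0.388, abs=1e-12)
        # all rows pure -> zero index
        assert standard_gini_index(table2_left) == 0.0
        single = ContingencyTable(np.array([[4, 6, 30]]))
        assert standard_gini_index(single) == pytest.approx(
            gini_impurity([4, 6, 30]))

    def test_dataset_impurity_and_split(self, table1):
        assert gini_dataset(table1) == pytest.approx(0.58, abs=1e-12)
        assert split_status(table1) == pytest.approx(0.64, abs=1e-12)
        single = ContingencyTable(np.array([[4, 6, 30]]))
        assert split_status(single) == 0.0

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_split_equal_ranges_closed_form(self, m):
        t = ContingencyTable(np.full((m, 2), 5))
        assert split_status(t) == pytest.approx(1 - 1 / m, abs=1e-12)


class TestClassOrder:
    def test_ascending_totals(self, table1):
        assert class_order(table1).tolist() == [0, 1, 2]

    def test_permuted_totals(self):
        t = ContingencyTable(np.array([[50, 10, 40]]))
        assert class_order(t).tolist() == [1, 2, 0]

    def test_stable_tie_break(self):
        t = ContingencyTable(np.array([[5, 5, 5]]))
        assert class_order(t).tolist() == [0, 1, 2]


class TestLorenz:
    def test_equality_polygon_area(self, table1):
        assert equality_polygon(table1).area == pytest.approx(1.1 / 3,
                                                              abs=1e-12)

    def test_signed_coefficients_differ_for_permuted_rows(self, table1):
        g1 = lorenz_coefficient(table1.counts[0], table1)
        g2 = lorenz_coefficient(table1.counts[1], table1)
        g3 = lorenz_coefficient(table1.counts[2], table1)
        assert g1 == pytest.approx(-5 / 22, abs=1e-12)   # ~ -0.22727
        assert g2 == pytest.approx(9 / 22, abs=1e-12)    # ~ +0.40909
        assert g3 == pytest.approx(-8 / 22, abs=1e-12)   # ~ -0.36364
        # the permuted rows share identical impurity but not coefficients
        assert gini_impurity(table1.counts[0]) == gini_impurity(
            table1.counts[1])
        assert g1 != g2

    def test_row_matching_dataset_profile_scores_zero(self, table1):
        g = lorenz_coefficient(table1.col_totals * 2, table1)
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_curve_monotone(self, table1):
        c = lorenz_curve(table1.counts[1], table1)
        assert (np.diff(c.ordinates) >= 0).all()
        assert c.ordinates[0] == 0 and c.ordinates[-1] == pytest.approx(1)


class TestAlpha:
    def test_reference_values(self, table1):
        # hand derivation: alpha_i = m (1+|g_i|) / sum(1+|g_j|) with
        # |g| = (5, 9, 8)/22, so alpha = 3*(27, 31, 30)/88
        expected = 3 * np.array([27, 31, 30]) / 88
        assert alpha_weights(table1) == pytest.approx(expected, abs=1e-12)

    def test_uniform_when_rows_match_profile(self):
        t = ContingencyTable(np.array([[1, 4, 5], [2, 8, 10], [3, 12, 15]]))
        assert alpha_weights(t) == pytest.approx(np.ones(3), abs=1e-12)

    def test_single_row(self):
        t = ContingencyTable(np.array([[4, 6, 30]]))
        assert alpha_weights(t) == pytest.approx([1.0])

    def test_sums_to_m_and_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = random_table(rng)
            a = alpha_weights(t)
            assert a.sum() == pytest.approx(t.m, abs=1e-9)
            assert (a >= 0).all()


class TestDelta:
    def test_row_distance(self):
        assert row_distance([1, 0, 0], [0, 1, 0]) == 1.0
        assert row_distance([2, 4, 6], [1, 2, 3]) == 0.0
        assert row_distance([3, 0, 0], [4, 0, 0]) == 0.0
        with pytest.raises(ValueError):
            row_distance([0, 0], [1, 0])

    def test_reference_vectors(self, table2_left, table2_right):
        assert delta_weights(table2_left) == pytest.approx([0, 0, 0, 0],
                                                           abs=1e-12)
        assert delta_weights(table2_right) == pytest.approx([1, 0.5, 0, 0],
                                                            abs=1e-12)
        # the harmonic (sorted) gene is emphasised more overall
        assert (delta_weights(table2_right).sum()
                > delta_weights(table2_left).sum())

    def test_identical_rows_and_single_row(self):
        t = ContingencyTable(np.array([[1, 2], [2, 4], [4, 8]]))
        assert delta_weights(t) == pytest.approx([1, 1, 1])
        t1 = ContingencyTable(np.array([[1, 2]]))
        assert delta_weights(t1) == pytest.approx([1.0])

    def test_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            d = delta_weights(random_table(rng))
            assert ((d >= 0) & (d <= 1)).all()


class TestWeightedIndex:
    def test_uniform_weights_reduce_to_standard(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            t = random_table(rng)
            w = weighted_gini_index(t, alpha=np.ones(t.m), delta=np.ones(t.m))
            assert w == pytest.approx(standard_gini_index(t), abs=1e-12)

    def test_pure_rows_give_zero(self, table2_left, table2_right):
        assert weighted_gini_index(table2_left) == 0.0
        assert weighted_gini_index(table2_right) == 0.0

    def test_weighting_changes_nonuniform_case(self, table1):
        assert weighted_gini_index(table1) != pytest.approx(0.388, abs=1e-6)

    def test_scale_invariance_of_weights(self, table1):
        a = alpha_weights(table1)
        d = delta_weights(table1)
        assert weighted_gini_index(table1, a, d) == pytest.approx(
            weighted_gini_index(table1, 7.3 * a, 0.2 * d), abs=1e-12)


class TestScore:
    def test_reference_composition(self, table1):
        s = lorenzgini_score(table1, use_alpha=False, use_delta=False)
        assert s.gini_D == pytest.approx(0.58, abs=1e-12)
        assert s.lorenzgini == pytest.approx((0.58 - 0.388) / 0.64, abs=1e-12)

    def test_single_range_scores_zero(self):
        t = ContingencyTable(np.array([[4, 6, 30]]))
        s = lorenzgini_score(t)
        assert s.split == 0.0 and s.lorenzgini == 0.0

    def test_fields_consistent(self, table1):
        s = lorenzgini_score(table1)
        assert len(s.alpha) == len(s.delta) == table1.m
        assert 0 <= s.gini_D <= 1 - 1 / table1.n
        assert 0 <= s.split < 1
        assert s.lorenzgini == pytest.approx(s.delta_gini / s.split)

    def test_class_permutation_invariance(self, table1):
        # permuting class columns (labels permuted the same way) must not
        # change the score when column totals are distinct
        perm = [2, 0, 1]
        permuted = ContingencyTable(table1.counts[:, perm])
        s0 = lorenzgini_score(table1)
        s1 = lorenzgini_score(permuted)
        assert s1.lorenzgini == pytest.approx(s0.lorenzgini, abs=1e-12)
        assert s1.gini_A_weighted == pytest.approx(s0.gini_A_weighted,
                                                   abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_score_bounds_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng)
        s = lorenzgini_score(t)
        assert 0.0 <= s.gini_D <= 1 - 1 / t.n + 1e-12
        assert 0.0 <= s.split < 1.0
        assert np.isfinite(s.lorenzgini)


def _disc_from_codes(codes, labels, class_set):
    codes = np.asarray(codes)
    return DiscretizedMatrix(
        [f"g{i}" for i in range(codes.shape[0])],
        [f"s{j}" for j in range(codes.shape[1])],
        codes, labels, class_set,
        [int(c.max()) + 1 for c in codes],
        [np.arange(int(c.max()), dtype=float) + 0.5 for c in codes])


class TestRankGenes:
    def test_predictive_gene_ranks_first(self):
        rng = np.random.default_rng(11)
        labels = ["A"] * 30 + ["B"] * 30
        lab = np.array([0] * 30 + [1] * 30)
        codes = [lab]  # gene 0 predicts the class exactly
        for _ in range(99):
            codes.append(rng.permutation(lab))
        disc = _disc_from_codes(np.array(codes), labels, ["A", "B"])
        table = rank_genes(disc, top_k=100)
        assert table.gene_ids[0] == "g0"
        # brute-force: no other gene scores higher
        scores = {g: s.lorenzgini for g, s in table}
        assert all(scores["g0"] >= v for v in scores.values())

    def test_tie_break_alphabetical_and_topk_clamp(self):
        labels = ["A"] * 4 + ["B"] * 4
        same = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        disc = _disc_from_codes(np.array([same, same]), labels, ["A", "B"])
        table = rank_genes(disc, top_k=10)
        assert table.gene_ids == ["g0", "g1"]  # full ranking, alphabetical

    def test_invariant_under_gene_order_permutation(self):
        rng = np.random.default_rng(13)
        labels = list(rng.choice(["A", "B", "C"], size=40))
        codes = rng.integers(0, 3, size=(20, 40))
        disc = _disc_from_codes(codes, labels, ["A", "B", "C"])
        perm = rng.permutation(20)
        disc_p = _disc_from_codes(codes[perm], labels, ["A", "B", "C"])
        # same gene ids attached to the same rows
        disc_p.gene_ids = [disc.gene_ids[i] for i in perm]
        r0 = rank_genes(disc, top_k=20)
        r1 = rank_genes(disc_p, top_k=20)
        assert r0.gene_ids == r1.gene_ids
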