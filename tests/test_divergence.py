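import itertools

import numpy as np
import pytest
from scipy import stats

from paracns.classify import ParalogPair
from oracles import fisher_oracle

from paracns.divergence import (
    OrthologRecord,
    compare_correlations,
    fisher_exact_two_sided,
    group_dnds_test,
    ortholog_retention_table,
    permutation_rho_distribution,
    select_ortholog,
    spearman_rho,
)


class TestSelectOrtholog:
    def rec(self, o, ident, ds):
        return OrthologRecord(gene="g", ortholog=o, pct_identity=ident, dN=0.1, dS=ds)

    def test_higher_identity_wins(self):
        best = select_ortholog([self.rec("o1", 90, 0.10), self.rec("o2", 95, 0.30)])
        assert best.ortholog == "o2"

    def test_identity_tie_broken_by_lowest_ds(self):
        best = select_ortholog([self.rec("o1", 90, 0.30), self.rec("o2", 90, 0.10)])
        assert best.ortholog == "o2"

    def test_single_candidate(self):
        only = self.rec("o1", 80, 0.2)
        assert select_ortholog([only]) is only

    def test_full_tie_broken_lexicographically(self):
        best = select_ortholog([self.rec("oB", 90, 0.1), self.rec("oA", 90, 0.1)])
        assert best.ortholog == "oA"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_ortholog([])


class TestRetentionTable:
    def make_diff_pair(self, i, lower, higher):
        return ParalogPair(gene_a=lower, gene_b=higher, group="differential",
                           higher=higher, lower=lower)

    def test_row_sums_equal_pair_count(self):
        pairs = [self.make_diff_pair(i, f"l{i}", f"h{i}") for i in range(3)]
        presence = {"l0": True, "l1": False, "l2": False,
                    "h0": True, "h1": True, "h2": True}
        table = ortholog_retention_table(pairs, presence)
        assert table.tolist() == [[1, 2], [3, 0]]
        assert table.sum(axis=1).tolist() == [3, 3]

    def test_all_present(self):
        pairs = [self.make_diff_pair(i, f"l{i}", f"h{i}") for i in range(4)]
        presence = {g: True for p in pairs for g in (p.lower, p.higher)}
        assert ortholog_retention_table(pairs, presence).tolist() == [[4, 0], [4, 0]]

    def test_missing_presence_names_pair(self):
        pairs = [self.make_diff_pair(0, "l0", "h0")]
        with pytest.raises(ValueError, match="h0"):
            ortholog_retention_table(pairs, {"l0": True})


class TestFisherExact:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact_two_sided([[10, 0], [10, 0]]) == pytest.approx(1.0)

    def test_symmetric_table_enumeration(self):
        # margins (4,4),(4,4): p = 34/70
        assert fisher_exact_two_sided([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[1, -1], [0, 2]])

    def test_matches_enumeration_oracle_exhaustively(self):
        # every 2x2 table with total N <= 16
        for n in range(1, 17):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        assert fisher_exact_two_sided(table) == pytest.approx(
                            fisher_oracle(table), abs=1e-8
                        ), table

    def test_matches_enumeration_oracle_random_large(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(17, 41))
            cuts = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            table = [[a, b], [c, d]]
            assert fisher_exact_two_sided(table) == pytest.approx(
                fisher_oracle(table), abs=1e-8
            ), table


class TestGroupDnDs:
    def test_hand_computed_h_statistic(self):
        res = group_dnds_test({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.h_statistic == pytest.approx(7.2)

    def test_identical_groups_not_significant(self):
        g = [0.1, 0.2, 0.3, 0.4]
        res = group_dnds_test({"a": g, "b": g, "c": g})
        assert all(p == pytest.approx(1.0) for p in res.pairwise_p.values())

    def test_group_separation_detected(self):
        rng = np.random.default_rng(1)
        res = group_dnds_test(
            {
                "similar": rng.gamma(6, 0.17 / 6, 150),
                "higher": rng.gamma(6, 0.13 / 6, 150),
                "lower": rng.gamma(6, 0.24 / 6, 150),
            }
        )
        assert res.p_value < 0.001
        assert res.pairwise_p[("higher", "lower")] < 0.001
        assert res.medians["lower"] > res.medians["similar"] > res.medians["higher"]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="b"):
            group_dnds_test({"a": [1, 2], "b": [1]})


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, x).coefficient == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1]).coefficient == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        res = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.coefficient == pytest.approx(0.6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])


class TestPermutationDistribution:
    def test_selection_invariant_input_degenerates(self):
        pair_z = [((0.1 * i, 0.2 * i), (0.1 * i, 0.2 * i)) for i in range(5)]
        dist = permutation_rho_distribution(pair_z, iterations=200, seed=0)
        assert dist.interval_95 == (dist.median, dist.median)

    def test_matches_exhaustive_enumeration_on_three_pairs(self):
        rng = np.random.default_rng(3)
        pair_z = [((rng.normal(), rng.normal()), (rng.normal(), rng.normal()))
                  for _ in range(3)]
        exact = set()
        for bits in itertools.product([0, 1], repeat=3):
            zs = [pair_z[i][b] for i, b in enumerate(bits)]
            rho = stats.spearmanr([z[0] for z in zs], [z[1] for z in zs])[0]
            exact.add(round(rho, 12))
        dist = permutation_rho_distribution(pair_z, iterations=2000, seed=1)
        observed = {round(c, 12) for c in dist.coefficients}
        assert observed <= exact
        assert observed == exact  # 2000 draws cover all 8 selections

    def test_deterministic_under_seed(self):
        pair_z = [((i, i + 0.5), (i + 0.1, i)) for i in range(6)]
        d1 = permutation_rho_distribution(pair_z, iterations=100, seed=7)
        d2 = permutation_rho_distribution(pair_z, iterations=100, seed=7)
        assert np.array_equal(d1.coefficients, d2.coefficients)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            permutation_rho_distribution([], iterations=10, seed=0)


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations(0.5, 100, 0.5, 50)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_direct_evaluation(self):
        z, p = compare_correlations(0.6, 15134, 0.49, 109)
        assert z == pytest.approx(1.61, abs=0.01)
        assert p == pytest.approx(0.107, abs=0.005)

    def test_antisymmetry(self):
        z1, p1 = compare_correlations(0.6, 40, 0.3, 60)
        z2, p2 = compare_correlations(0.3, 60, 0.6, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.4, 100)
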