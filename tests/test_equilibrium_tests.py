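import numpy as np
import pytest

from oracles import contingency_p, hwe_enumeration_p
from xstrpop.equilibrium_tests import (
    MCParams, bonferroni, contingency_exact_test,
    exact_population_differentiation, hwe_exact_test, ld_exact_test_males,
    ld_test_females, _em_two_locus,
)


class TestHweExact:
    def test_monomorphic(self):
        res = hwe_exact_test({("A", "A"): 7})
        assert res.p_value == 1.0
        assert "degenerate" in res.flags

    def test_matches_enumeration_oracle_simple(self):
        counts = {("A", "A"): 1, ("A", "B"): 2, ("B", "B"): 1}
        res = hwe_exact_test(counts)
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(hwe_enumeration_p(counts), abs=1e-12)

    @pytest.mark.parametrize("counts", [
        {("A", "A"): 3, ("B", "B"): 2},
        {("A", "A"): 2, ("A", "B"): 1, ("B", "B"): 2},
        {("A", "B"): 2, ("B", "C"): 2, ("A", "C"): 1},
        {("A", "A"): 1, ("A", "B"): 1, ("B", "C"): 2, ("C", "C"): 1},
    ])
    def test_matches_enumeration_oracle(self, counts):
        res = hwe_exact_test(counts)
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(hwe_enumeration_p(counts), abs=1e-10)

    def test_mc_agrees_with_enumeration(self):
        counts = {("A", "A"): 6, ("A", "B"): 2, ("B", "B"): 6, ("A", "C"): 1, ("C", "C"): 2}
        exact = hwe_exact_test(counts).p_value
        mc = hwe_exact_test(counts, max_tables=1, seed=11, mc=MCParams(steps=40_000))
        assert mc.method == "monte-carlo"
        assert abs(mc.p_value - exact) <= 3 * mc.se

    def test_mc_requires_seed(self):
        counts = {("A", "A"): 20, ("A", "B"): 20, ("B", "B"): 20}
        with pytest.raises(ValueError, match="seed"):
            hwe_exact_test(counts, max_tables=1)

    def test_mc_deterministic_in_seed(self):
        counts = {("A", "A"): 10, ("A", "B"): 4, ("B", "B"): 10}
        a = hwe_exact_test(counts, max_tables=1, seed=5, mc=MCParams(steps=5000))
        b = hwe_exact_test(counts, max_tables=1, seed=5, mc=MCParams(steps=5000))
        assert a.p_value == b.p_value

    def test_requires_data(self):
        with pytest.raises(ValueError):
            hwe_exact_test({})


class TestMaleLd:
    def test_fisher_extreme(self):
        res = ld_exact_test_males(["A"] * 5 + ["B"] * 5, ["x"] * 5 + ["y"] * 5)
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_monomorphic_flagged(self):
        res = ld_exact_test_males(["A"] * 6, ["x", "y"] * 3)
        assert res.p_value == 1.0
        assert "degenerate" in res.flags

    def test_perfect_coupling_n50(self):
        a = ["A"] * 25 + ["B"] * 25
        res = ld_exact_test_males(a, a)
        assert res.p_value < 1e-4

    @pytest.mark.parametrize("table", [
        [[3, 1], [1, 3]],
        [[2, 0, 2], [0, 3, 0]],
        [[1, 2], [2, 1], [2, 0]],
    ])
    def test_matches_assignment_oracle(self, table):
        res = contingency_exact_test(table)
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(contingency_p(table), abs=1e-10)

    def test_mc_agrees_with_enumeration(self):
        table = [[8, 3, 2], [2, 7, 3], [1, 2, 6]]
        exact = contingency_exact_test(table).p_value
        mc = contingency_exact_test(table, max_tables=1, seed=3, mc=MCParams(steps=40_000))
        assert abs(mc.p_value - exact) <= 3 * mc.se

    def test_unpaired_vectors_rejected(self):
        with pytest.raises(ValueError):
            ld_exact_test_males(["A"], ["x", "y"])

    def test_missing_pairs_dropped(self):
        res = ld_exact_test_males(["A", "B", None, "A", "B"],
                                  ["x", "y", "x", None, "y"])
        assert res.p_value <= 1.0


class TestFemaleLd:
    def test_single_individual_error(self):
        with pytest.raises(ValueError, match="two complete"):
            ld_test_females([("a", "a")], [("x", "x")], seed=1)

    def test_seed_required(self):
        g = [("a", "a"), ("b", "b")]
        h = [("x", "x"), ("y", "y")]
        with pytest.raises(ValueError, match="seed"):
            ld_test_females(g, h)

    def test_em_on_unambiguous_data_equals_counts(self):
        genos = [((0, 0), (0, 0))] * 6 + [((1, 1), (1, 1))] * 2
        h, _, converged = _em_two_locus(genos, 2, 2)
        assert converged
        np.testing.assert_allclose(h, [[0.75, 0.0], [0.0, 0.25]], atol=1e-9)

    def test_coupled_loci_significant(self):
        a = [("p", "p")] * 10 + [("q", "q")] * 10
        res = ld_test_females(a, [("x" if g == ("p", "p") else "y",) * 2 for g in a],
                              permutations=199, seed=7)
        assert res.p_value < 0.02

    def test_type_one_error_calibrated(self):
        # independent haplotypes: rejection rate at alpha=0.05 stays near alpha
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            ga = [tuple(sorted(rng.choice(["a", "b"], 2, p=[0.6, 0.4]))) for _ in range(30)]
            gb = [tuple(sorted(rng.choice(["x", "y"], 2, p=[0.3, 0.7]))) for _ in range(30)]
            res = ld_test_females(ga, gb, permutations=99,
                                  seed=int(rng.integers(2 ** 31)))
            if res.p_value < 0.05:
                rejections += 1
        assert rejections / n_sims <= 0.08

    def test_deterministic_in_seed(self):
        rng = np.random.default_rng(0)
        ga = [tuple(sorted(rng.choice(["a", "b"], 2))) for _ in range(20)]
        gb = [tuple(sorted(rng.choice(["x", "y"], 2))) for _ in range(20)]
        r1 = ld_test_females(ga, gb, permutations=99, seed=9)
        r2 = ld_test_females(ga, gb, permutations=99, seed=9)
        assert r1.p_value == r2.p_value


class TestDifferentiation:
    def test_identical_counts(self):
        res = exact_population_differentiation({"A": 5, "B": 5}, {"A": 5, "B": 5})
        assert res.p_value == 1.0

    def test_disjoint_fisher(self):
        res = exact_population_differentiation({"A": 5}, {"B": 5})
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_empty_population_error(self):
        with pytest.raises(ValueError):
            exact_population_differentiation({"A": 5}, {})

    def test_matches_oracle(self):
        c1, c2 = {"A": 4, "B": 2, "C": 1}, {"A": 1, "B": 3, "C": 3}
        res = exact_population_differentiation(c1, c2)
        table = [[4, 1], [2, 3], [1, 3]]
        assert res.p_value == pytest.approx(contingency_p(table), abs=1e-10)


class TestBonferroni:
    def test_paper_locus_example(self):
        res = bonferroni([0.0027], alpha=0.05, m=12)
        assert res.threshold == pytest.approx(0.0041667, abs=1e-6)
        assert res.flags == [True]

    def test_boundary_is_not_significant(self):
        res = bonferroni([0.05 / 12], alpha=0.05, m=12)
        assert res.flags == [False]

    def test_sixty_six_pairs(self):
        res = bonferroni([0.5], alpha=0.05, m=66)
        assert res.threshold == pytest.approx(0.000758, abs=1e-6)

    def test_m_defaults_to_len(self):
        res = bonferroni([0.01, 0.2])
        assert res.m == 2 and res.flags == [True, False]

    def test_m_must_be_positive(self):
        with pytest.raises(ValueError):
            bonferroni([], alpha=0.05, m=0)
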