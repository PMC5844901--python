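import math

import numpy as np
import pytest

from oracles import fst_two_pop_oracle
from xstrpop.equilibrium_tests import bonferroni
from xstrpop.population_comparison import (
    fst_significance_matrix, nei_unbiased_distance, pairwise_fst,
)
from xstrpop.synthetic_data import (
    balding_nichols_frequencies, simulate_frequencies,
)


class TestPairwiseFst:
    def test_fixation(self):
        r = pairwise_fst({"p1": {"L1": {"A": 10}}, "p2": {"L1": {"B": 10}}})
        assert r.multi_locus[("p1", "p2")] == pytest.approx(1.0)

    def test_identical_counts_nonpositive_not_truncated(self):
        r = pairwise_fst({"p1": {"L1": {"A": 5, "B": 5}},
                          "p2": {"L1": {"A": 5, "B": 5}}})
        assert r.multi_locus[("p1", "p2")] <= 0.0  # preserved, not floored

    @pytest.mark.parametrize("c1,c2", [
        ({"A": 8, "B": 2}, {"A": 3, "B": 7}),
        ({"A": 5, "B": 5}, {"A": 9, "B": 1}),
        ({"A": 12, "B": 4}, {"A": 2, "B": 10}),
    ])
    def test_matches_explicit_sum_oracle(self, c1, c2):
        r = pairwise_fst({"p1": {"L1": c1}, "p2": {"L1": c2}})
        assert r.per_locus[("p1", "p2")]["L1"] == pytest.approx(
            fst_two_pop_oracle(c1, c2), abs=1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="no chromosomes"):
            pairwise_fst({"p1": {"L1": {"A": 5}}, "p2": {"L1": {}}})

    def test_permutation_needs_seed(self):
        counts = {"p1": {"L1": {"A": 5, "B": 5}}, "p2": {"L1": {"A": 5, "B": 5}}}
        with pytest.raises(ValueError):
            pairwise_fst(counts, permutations=10)

    def test_permutation_deterministic(self):
        counts = {"p1": {"L1": {"A": 9, "B": 1}}, "p2": {"L1": {"A": 2, "B": 8}}}
        a = pairwise_fst(counts, permutations=199, seed=4)
        b = pairwise_fst(counts, permutations=199, seed=4)
        assert a.p_values == b.p_values

    def test_divergent_pair_significant(self):
        counts = {"p1": {"L1": {"A": 95, "B": 5}}, "p2": {"L1": {"A": 10, "B": 90}}}
        r = pairwise_fst(counts, permutations=199, seed=1)
        assert r.p_values[("p1", "p2")] < 0.01

    def test_distance_matrix_floors_negatives(self):
        counts = {"p1": {"L1": {"A": 5, "B": 5}}, "p2": {"L1": {"A": 5, "B": 5}}}
        r = pairwise_fst(counts)
        m = r.to_distance_matrix()
        assert m[("p1", "p2")] == 0.0

    def test_multilocus_is_component_ratio(self):
        counts = {
            "p1": {"L1": {"A": 8, "B": 2}, "L2": {"A": 5, "B": 5}},
            "p2": {"L1": {"A": 2, "B": 8}, "L2": {"A": 5, "B": 5}},
        }
        r = pairwise_fst(counts)
        ml = r.multi_locus[("p1", "p2")]
        mean = np.mean(list(r.per_locus[("p1", "p2")].values()))
        assert ml != pytest.approx(mean)  # modes genuinely differ
        assert r.to_distance_matrix(mode="locus_mean")[("p1", "p2")] == pytest.approx(
            max(mean, 0.0))

    def test_fst_zero_estimate_near_zero(self):
        rng = np.random.default_rng(3)
        counts = {"p1": {}, "p2": {}}
        for l in range(12):
            p = simulate_frequencies(8, seed=rng)
            for pop in counts:
                x = rng.multinomial(500, p)
                counts[pop][f"L{l}"] = {i: int(v) for i, v in enumerate(x) if v}
        est = pairwise_fst(counts).multi_locus[("p1", "p2")]
        assert abs(est) < 0.01


class TestNeiDistance:
    def test_identical_no_correction(self):
        r = nei_unbiased_distance([[0.3, 0.7]], [[0.3, 0.7]], bias_correction=False)
        assert r.d == pytest.approx(0.0, abs=1e-14)

    def test_hand_calculation(self):
        r = nei_unbiased_distance([[0.9, 0.1]], [[0.1, 0.9]], bias_correction=False)
        assert r.jx == pytest.approx(0.82)
        assert r.jxy == pytest.approx(0.18)
        assert r.d == pytest.approx(1.5163, abs=5e-5)

    def test_disjoint_alleles_infinite(self):
        r = nei_unbiased_distance([[1.0, 0.0]], [[0.0, 1.0]], bias_correction=False)
        assert math.isinf(r.d) and r.infinite

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        fx = [rng.dirichlet(np.ones(5)) for _ in range(3)]
        fy = [rng.dirichlet(np.ones(5)) for _ in range(3)]
        a = nei_unbiased_distance(fx, fy, 100, 120)
        b = nei_unbiased_distance(fy, fx, 120, 100)
        assert a.d == pytest.approx(b.d, abs=1e-12)

    def test_nonnegative_without_correction(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fx = [rng.dirichlet(np.ones(4))]
            fy = [rng.dirichlet(np.ones(4))]
            assert nei_unbiased_distance(fx, fy, bias_correction=False).d >= -1e-12

    def test_correction_can_go_negative_and_is_preserved(self):
        # identical samples: unbiased within-identity drops below the raw
        # cross-identity, giving a small negative D
        f = [[0.5, 0.5]]
        r = nei_unbiased_distance(f, f, 10, 10, bias_correction=True)
        assert r.d < 0.0

    def test_correction_requires_sizes(self):
        with pytest.raises(ValueError):
            nei_unbiased_distance([[0.5, 0.5]], [[0.5, 0.5]])


class TestSignificanceMatrix:
    def _result(self, pvals):
        counts = {"p1": {"L1": {"A": 5, "B": 5}}, "p2": {"L1": {"A": 5, "B": 5}}}
        r = pairwise_fst(counts, permutations=9, seed=0)
        r.p_per_locus = pvals
        return r

    def test_all_ones_no_significance(self):
        r = self._result({("p1", "p2"): {f"L{i}": 1.0 for i in range(12)}})
        s = fst_significance_matrix(r)
        assert s.counts[("p1", "p2")] == 0

    def test_four_significant_loci_counted(self):
        ps = {f"L{i}": (0.01 if i < 4 else 0.5) for i in range(12)}
        s = fst_significance_matrix(self._result({("p1", "p2"): ps}))
        assert s.counts[("p1", "p2")] == 4

    def test_bonferroni_mode_matches_bonferroni(self):
        ps = {f"L{i}": 0.003 * (i + 1) for i in range(12)}
        s = fst_significance_matrix(self._result({("p1", "p2"): ps}),
                                    alpha=0.05, mode="bonferroni")
        ref = bonferroni([ps[f"L{i}"] for i in range(12)], 0.05, 12)
        assert [s.flags[("p1", "p2")][f"L{i}"] for i in range(12)] == ref.flags

    def test_requires_pvalues(self):
        counts = {"p1": {"L1": {"A": 5, "B": 5}}, "p2": {"L1": {"A": 5, "B": 5}}}
        with pytest.raises(ValueError):
            fst_significance_matrix(pairwise_fst(counts))


class TestBaldingNicholsRecovery:
    def test_mean_estimate_recovers_target(self):
        # scaled-down version of the acceptance property (30 reps here)
        rng = np.random.default_rng(11)
        target = 0.05
        ests = []
        for _ in range(30):
            counts = {"p1": {}, "p2": {}}
            for l in range(12):
                anc = simulate_frequencies(10, seed=rng)
                f1, f2 = balding_nichols_frequencies(anc, target, 2, seed=rng)
                for pop, f in (("p1", f1), ("p2", f2)):
                    x = rng.multinomial(200, f)
                    counts[pop][f"L{l}"] = {i: int(v) for i, v in enumerate(x) if v}
            ests.append(pairwise_fst(counts).multi_locus[("p1", "p2")])
        assert abs(np.mean(ests) - target) <= 0.3 * target
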