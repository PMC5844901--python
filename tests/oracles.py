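"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: exact-test p-values
come from enumerating equally likely matchings/assignments, variance
components from explicit sums, and exclusion probabilities from direct
Monte Carlo simulation of the family scenarios.
"""

from __future__ import annotations

import math
from collections import Counter
from fractions import Fraction

import numpy as np
from sympy.utilities.iterables import multiset_permutations

_TOL = 1e-9


def hwe_enumeration_p(genotype_counts: dict) -> float:
    """Exact conditional HWE p-value by enumerating all perfect matchings of
    the (distinguishable) allele copies into genotypes."""
    alleles: list = []
    for (a, b), c in genotype_counts.items():
        for _ in range(c):
            alleles.extend([a, b])
    n = len(alleles) // 2

    def canon(table: Counter) -> tuple:
        return tuple(sorted((k, v) for k, v in table.items() if v > 0))

    obs_counter: Counter = Counter()
    for pair, c in genotype_counts.items():
        obs_counter[tuple(sorted(pair))] += c
    obs = canon(obs_counter)

    table_counts: Counter = Counter()

    def rec(remaining: tuple, current: Counter):
        if not remaining:
            table_counts[canon(current)] += 1
            return
        first = remaining[0]
        rest = remaining[1:]
        seen = set()
        for i, other in enumerate(rest):
            pair = tuple(sorted((first, other)))
            # pair with each distinct *position*; positions are distinguishable
            current[pair] += 1
            rec(rest[:i] + rest[i + 1:], current)
            current[pair] -= 1
    rec(tuple(alleles), Counter())

    total = sum(table_counts.values())
    obs_prob = table_counts[obs] / total
    p = sum(c for t, c in table_counts.items()
            if c / total <= obs_prob * (1 + _TOL)) / total
    return p


def contingency_p(table) -> float:
    """Exact conditional independence p-value by enumerating all equally
    likely assignments of column labels to row labels."""
    table = np.asarray(table, dtype=int)
    rows = [i for i, c in enumerate(table.sum(axis=1)) for _ in range(c)]
    cols = [j for j, c in enumerate(table.sum(axis=0)) for _ in range(c)]
    r, c = table.shape

    def canon(row_vec, col_vec) -> tuple:
        m = np.zeros((r, c), dtype=int)
        for i, j in zip(row_vec, col_vec):
            m[i, j] += 1
        return tuple(m.ravel())

    obs = tuple(table.ravel())
    counts: Counter = Counter()
    for perm in multiset_permutations(cols):
        counts[canon(rows, perm)] += 1
    total = sum(counts.values())
    obs_prob = counts[obs] / total
    return sum(v for t, v in counts.items() if v / total <= obs_prob * (1 + _TOL)) / total


def fst_two_pop_oracle(counts_a: dict, counts_b: dict) -> float:
    """Haploid two-population Fst by explicit sums (no matrix shortcuts)."""
    alleles = sorted(set(counts_a) | set(counts_b))
    n1 = sum(counts_a.values())
    n2 = sum(counts_b.values())
    n = n1 + n2
    sigma_a = sigma_w = 0.0
    for al in alleles:
        p1 = counts_a.get(al, 0) / n1
        p2 = counts_b.get(al, 0) / n2
        pbar = (counts_a.get(al, 0) + counts_b.get(al, 0)) / n
        msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / 1.0
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - 2)
        n_c = (n - (n1 ** 2 + n2 ** 2) / n) / 1.0
        sigma_a += (msp - msg) / n_c
        sigma_w += msg
    return sigma_a / (sigma_a + sigma_w)


def pd_f_oracle(freqs) -> float:
    """1 - sum of squared HWE female genotype frequencies, by genotype
    enumeration."""
    p = list(freqs)
    k = len(p)
    s = 0.0
    for i in range(k):
        for j in range(i, k):
            g = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            s += g * g
    return 1.0 - s


# ---------------------------------------------------------------------------
# Monte Carlo exclusion simulations
# ---------------------------------------------------------------------------

def _obligate_membership(x, c1, c2, m1, m2):
    """Vectorized: is allele x in the obligate paternal set for child (c1,c2)
    and mother (m1,m2)?"""
    mother_has_c1 = (m1 == c1) | (m2 == c1)
    mother_has_c2 = (m1 == c2) | (m2 == c2)
    return ((x == c2) & mother_has_c1) | ((x == c1) & mother_has_c2)


def mc_duo_exclusion(freqs, n_sims: int, seed: int) -> tuple[float, float]:
    """Father/daughter duo: exclusion chance of a random hemizygous male."""
    rng = np.random.default_rng(seed)
    p = np.asarray(list(freqs), dtype=float)
    k = len(p)
    d1 = rng.choice(k, size=n_sims, p=p)
    d2 = rng.choice(k, size=n_sims, p=p)
    man = rng.choice(k, size=n_sims, p=p)
    excl = (man != d1) & (man != d2)
    est = excl.mean()
    return float(est), float(math.sqrt(est * (1 - est) / n_sims))


def mc_trio_x_exclusion(freqs, n_sims: int, seed: int) -> tuple[float, float]:
    """Mother/daughter trio with hemizygous alleged father."""
    rng = np.random.default_rng(seed)
    p = np.asarray(list(freqs), dtype=float)
    k = len(p)
    m1 = rng.choice(k, size=n_sims, p=p)
    m2 = rng.choice(k, size=n_sims, p=p)
    trans = np.where(rng.random(n_sims) < 0.5, m1, m2)
    f = rng.choice(k, size=n_sims, p=p)
    man = rng.choice(k, size=n_sims, p=p)
    inc = _obligate_membership(man, trans, f, m1, m2)
    est = 1.0 - inc.mean()
    return float(est), float(math.sqrt(est * (1 - est) / n_sims))


def mc_trio_autosomal_exclusion(freqs, n_sims: int, seed: int) -> tuple[float, float]:
    """Classic trio with diploid mother, child and alleged father."""
    rng = np.random.default_rng(seed)
    p = np.asarray(list(freqs), dtype=float)
    k = len(p)
    m1 = rng.choice(k, size=n_sims, p=p)
    m2 = rng.choice(k, size=n_sims, p=p)
    trans = np.where(rng.random(n_sims) < 0.5, m1, m2)
    f = rng.choice(k, size=n_sims, p=p)
    g1 = rng.choice(k, size=n_sims, p=p)
    g2 = rng.choice(k, size=n_sims, p=p)
    inc1 = _obligate_membership(g1, trans, f, m1, m2)
    inc2 = _obligate_membership(g2, trans, f, m1, m2)
    est = 1.0 - (inc1 | inc2).mean()
    return float(est), float(math.sqrt(est * (1 - est) / n_sims))
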