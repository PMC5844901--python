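"""Exact tests: Hardy-Weinberg in females, two-locus LD in males and
females, and population differentiation, plus Bonferroni correction.

All tests condition on the observed allele counts.  Small problems are
solved by complete enumeration of the conditional null distribution; larger
ones by Monte Carlo sampling from the same conditional distribution
(independent resampling — random re-pairing of alleles for HWE, random
re-matching of the two allele vectors for contingency tests — which yields
unbiased p estimates with a clean binomial standard error).  The two-sided
p-value is the total null probability of outcomes no more probable than the
observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

_LOG_TOL = 1e-9  # tables within this log-probability of the observed count as "as extreme"


@dataclass(frozen=True)
class MCParams:
    """Monte Carlo sampling parameters.  ``steps`` independent samples are
    drawn from the conditional null distribution."""

    steps: int = 100_000
    chunk: int = 20_000


@dataclass
class TestResult:
    p_value: float
    method: str  # "enumeration" | "monte-carlo" | "permutation" | "degenerate"
    se: float | None = None
    steps: int | None = None
    seed: int | None = None
    statistic: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _log_fact(x) -> np.ndarray:
    return gammaln(np.asarray(x, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (females)
# ---------------------------------------------------------------------------

def _canon_genotype_counts(genotype_counts: Mapping) -> tuple[list, np.ndarray]:
    """Map genotype counts keyed by unordered allele pairs to an index matrix."""
    alleles: set = set()
    for pair in genotype_counts:
        if len(pair) != 2:
            raise ValueError(f"genotype key {pair!r} is not an allele pair")
        alleles.update(pair)
    order = sorted(alleles)
    idx = {a: i for i, a in enumerate(order)}
    k = len(order)
    mat = np.zeros((k, k), dtype=np.int64)
    for (a, b), c in genotype_counts.items():
        if c < 0:
            raise ValueError("negative genotype count")
        i, j = sorted((idx[a], idx[b]))
        mat[i, j] += c
    return order, mat


def _hwe_log_prob(mat: np.ndarray, log_const: float) -> float:
    """Conditional log-probability of a genotype table given allele counts:
    log[ n! * prod(a_i!) * 2^H / ((2n)! * prod(n_ij!)) ]."""
    het = mat.sum() - np.trace(mat)
    return log_const + het * math.log(2.0) - float(_log_fact(mat[np.triu_indices_from(mat)]).sum())


def _enumerate_hwe_tables(allele_counts: np.ndarray, cap: int):
    """Yield all symmetric genotype-count matrices with the given allele
    margins; raises _CapExceeded beyond *cap* tables."""
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    mat = np.zeros((k, k), dtype=np.int64)
    rem = allele_counts.copy()
    produced = 0

    def last_pair_for(i: int, pos: int) -> bool:
        # no pair at or after `pos` involves allele i
        return all(i != a and i != b for a, b in pairs[pos:])

    def rec(pos: int):
        nonlocal produced
        if pos == len(pairs):
            if rem.sum() == 0:
                produced += 1
                if produced > cap:
                    raise _CapExceeded
                yield mat.copy()
            return
        i, j = pairs[pos]
        if i == j:
            hi = rem[i] // 2
        else:
            hi = min(rem[i], rem[j])
        for c in range(hi + 1):
            mat[i, j] = c
            rem[i] -= 2 * c if i == j else c
            if i != j:
                rem[j] -= c
            feasible = True
            for a in (i, j):
                if rem[a] != 0 and last_pair_for(a, pos + 1):
                    feasible = False
                    break
            if feasible:
                yield from rec(pos + 1)
            rem[i] += 2 * c if i == j else c
            if i != j:
                rem[j] += c
            mat[i, j] = 0

    yield from rec(0)


class _CapExceeded(Exception):
    pass


def hwe_exact_test(genotype_counts: Mapping, *, mc: MCParams = MCParams(),
                   seed: int | None = None, max_tables: int = 200_000) -> TestResult:
    """Exact Hardy-Weinberg test on female diploid genotype counts.

    *genotype_counts* maps unordered allele pairs to counts.  Complete
    enumeration is used while the number of compatible tables stays within
    *max_tables*; otherwise Monte Carlo resampling (requires *seed*).
    Monomorphic data give p = 1 with a ``degenerate`` flag.
    """
    order, mat = _canon_genotype_counts(genotype_counts)
    n = int(mat.sum())
    if n < 1:
        raise ValueError("at least one genotype required")
    k = len(order)
    if k < 2:
        return TestResult(1.0, "degenerate", flags=("degenerate",))
    # allele i count = 2*n_ii + sum over j!=i of n_ij
    a = np.array([2 * mat[i, i] + sum(mat[min(i, j), max(i, j)] for j in range(k) if j != i)
                  for i in range(k)], dtype=np.int64)
    log_const = float(_log_fact(n) + _log_fact(a).sum() - _log_fact(2 * n))
    obs_lp = _hwe_log_prob(mat, log_const)

    try:
        total = 0.0
        p = 0.0
        for table in _enumerate_hwe_tables(a, max_tables):
            lp = _hwe_log_prob(table, log_const)
            pr = math.exp(lp)
            total += pr
            if lp <= obs_lp + _LOG_TOL:
                p += pr
        p /= total  # guard tiny float drift; total == 1 analytically
        return TestResult(min(p, 1.0), "enumeration")
    except _CapExceeded:
        pass

    if seed is None:
        raise ValueError("Monte Carlo HWE test requires an explicit seed")
    rng = np.random.default_rng(seed)
    # expand to the 2n-allele vector and re-pair at random
    vec = np.repeat(np.arange(k), a)
    hits = 0
    done = 0
    k2 = k * k
    while done < mc.steps:
        b = min(mc.chunk, mc.steps - done)
        perms = rng.permuted(np.tile(vec, (b, 1)), axis=1).reshape(b, n, 2)
        lo = perms.min(axis=2)
        hi = perms.max(axis=2)
        codes = lo * k + hi
        offset = np.arange(b)[:, None] * k2
        counts = np.bincount((codes + offset).ravel(), minlength=b * k2).reshape(b, k2)
        het = (perms[:, :, 0] != perms[:, :, 1]).sum(axis=1)
        lps = log_const + het * math.log(2.0) - _log_fact(counts).sum(axis=1)
        hits += int((lps <= obs_lp + _LOG_TOL).sum())
        done += b
    p = (hits + 1) / (mc.steps + 1)
    se = math.sqrt(p * (1 - p) / mc.steps)
    return TestResult(p, "monte-carlo", se=se, steps=mc.steps, seed=seed)


# ---------------------------------------------------------------------------
# contingency-table exact tests (male LD, population differentiation)
# ---------------------------------------------------------------------------

def _contingency_log_prob(table: np.ndarray, log_const: float) -> float:
    return log_const - float(_log_fact(table).sum())


def _enumerate_tables(rows: np.ndarray, cols: np.ndarray, cap: int):
    """All nonnegative integer matrices with the given margins."""
    r, c = len(rows), len(cols)
    mat = np.zeros((r, c), dtype=np.int64)
    colrem = cols.copy()
    produced = 0

    def rec(i: int):
        nonlocal produced
        if i == r - 1:
            if np.all(colrem <= rows[i]) and colrem.sum() == rows[i]:
                mat[i, :] = colrem
                produced += 1
                if produced > cap:
                    raise _CapExceeded
                yield mat.copy()
                mat[i, :] = 0
            return
        def fill(j: int, rem: int):
            if j == c - 1:
                if rem <= colrem[j]:
                    mat[i, j] = rem
                    colrem[j] -= rem
                    yield from rec(i + 1)
                    colrem[j] += rem
                    mat[i, j] = 0
                return
            for v in range(min(rem, colrem[j]) + 1):
                mat[i, j] = v
                colrem[j] -= v
                yield from fill(j + 1, rem - v)
                colrem[j] += v
                mat[i, j] = 0
        yield from fill(0, rows[i])

    yield from rec(0)


def contingency_exact_test(table: Sequence[Sequence[int]], *, mc: MCParams = MCParams(),
                           seed: int | None = None, max_tables: int = 200_000) -> TestResult:
    """Probability-ordering exact test of independence on an R x C count
    table (Fisher-Freeman-Halton style), conditioning on both margins."""
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("need a nonnegative 2-D count table")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return TestResult(1.0, "degenerate", flags=("degenerate",))
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = int(obs.sum())
    log_const = float(_log_fact(rows).sum() + _log_fact(cols).sum() - _log_fact(n))
    obs_lp = _contingency_log_prob(obs, log_const)

    try:
        p = 0.0
        total = 0.0
        for t in _enumerate_tables(rows, cols, max_tables):
            lp = _contingency_log_prob(t, log_const)
            pr = math.exp(lp)
            total += pr
            if lp <= obs_lp + _LOG_TOL:
                p += pr
        return TestResult(min(p / total, 1.0), "enumeration")
    except _CapExceeded:
        pass

    if seed is None:
        raise ValueError("Monte Carlo contingency test requires an explicit seed")
    rng = np.random.default_rng(seed)
    r, c = obs.shape
    a_codes = np.repeat(np.arange(r), rows)
    b_codes = np.repeat(np.arange(c), cols)
    rc = r * c
    hits = 0
    done = 0
    while done < mc.steps:
        b = min(mc.chunk, mc.steps - done)
        perms = rng.permuted(np.tile(b_codes, (b, 1)), axis=1)
        codes = a_codes[None, :] * c + perms
        offset = np.arange(b)[:, None] * rc
        counts = np.bincount((codes + offset).ravel(), minlength=b * rc).reshape(b, rc)
        lps = log_const - _log_fact(counts).sum(axis=1)
        hits += int((lps <= obs_lp + _LOG_TOL).sum())
        done += b
    p = (hits + 1) / (mc.steps + 1)
    se = math.sqrt(p * (1 - p) / mc.steps)
    return TestResult(p, "monte-carlo", se=se, steps=mc.steps, seed=seed)


def ld_exact_test_males(alleles_a: Sequence[Hashable], alleles_b: Sequence[Hashable],
                        *, mc: MCParams = MCParams(), seed: int | None = None,
                        max_tables: int = 200_000) -> TestResult:
    """Exact test of allelic independence between two loci typed in
    hemizygous males.  Pairs with a missing value are dropped."""
    if len(alleles_a) != len(alleles_b):
        raise ValueError("allele vectors must be paired")
    pairs = [(x, y) for x, y in zip(alleles_a, alleles_b) if x is not None and y is not None]
    if not pairs:
        raise ValueError("no complete observations")
    xs = sorted({x for x, _ in pairs})
    ys = sorted({y for _, y in pairs})
    if len(xs) < 2 or len(ys) < 2:
        return TestResult(1.0, "degenerate", flags=("degenerate",))
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: i for i, y in enumerate(ys)}
    table = np.zeros((len(xs), len(ys)), dtype=np.int64)
    for x, y in pairs:
        table[xi[x], yi[y]] += 1
    return contingency_exact_test(table, mc=mc, seed=seed, max_tables=max_tables)


def exact_population_differentiation(counts1: Mapping[Hashable, int],
                                     counts2: Mapping[Hashable, int], *,
                                     mc: MCParams = MCParams(), seed: int | None = None,
                                     max_tables: int = 200_000) -> TestResult:
    """Exact test that two populations share allele frequencies, on the
    alleles x populations count table (chromosome counts)."""
    if sum(counts1.values()) == 0 or sum(counts2.values()) == 0:
        raise ValueError("both populations need at least one chromosome")
    alleles = sorted(set(counts1) | set(counts2))
    table = [[counts1.get(a, 0), counts2.get(a, 0)] for a in alleles]
    return contingency_exact_test(table, mc=mc, seed=seed, max_tables=max_tables)


# ---------------------------------------------------------------------------
# female LD (EM haplotype frequencies + permutation)
# ---------------------------------------------------------------------------

def _collapse(genos: list[tuple[tuple[int, int], tuple[int, int]]]
              ) -> dict[tuple[tuple[int, int], tuple[int, int]], int]:
    classes: dict[tuple[tuple[int, int], tuple[int, int]], int] = {}
    for ga, gb in genos:
        key = (tuple(sorted(ga)), tuple(sorted(gb)))
        classes[key] = classes.get(key, 0) + 1
    return classes


def _class_loglik(hm: np.ndarray, classes: Mapping, ) -> float:
    ll = 0.0
    for ((a1, a2), (b1, b2)), w in classes.items():
        if a1 != a2 and b1 != b2:
            p = 2 * hm[a1, b1] * hm[a2, b2] + 2 * hm[a1, b2] * hm[a2, b1]
        else:
            mult = (2 if a1 != a2 else 1) * (2 if b1 != b2 else 1)
            p = mult * hm[a1, b1] * hm[a2, b2]
        ll += w * math.log(max(p, 1e-300))
    return ll


def _em_two_locus(genos: list[tuple[tuple[int, int], tuple[int, int]]], ka: int, kb: int,
                  max_iter: int = 500, tol: float = 1e-9) -> tuple[np.ndarray, float, bool]:
    """EM estimate of two-locus haplotype frequencies from unphased diploid
    genotypes.  Returns (haplotype frequency matrix, log-likelihood,
    converged).  Individuals are collapsed into genotype classes first."""
    classes = _collapse(genos)
    pa = np.zeros(ka)
    pb = np.zeros(kb)
    for ((a1, a2), (b1, b2)), w in classes.items():
        pa[a1] += w; pa[a2] += w
        pb[b1] += w; pb[b2] += w
    pa /= pa.sum()
    pb /= pb.sum()
    h = np.outer(pa, pb)

    prev = _class_loglik(h, classes)
    converged = False
    for _ in range(max_iter):
        exp = np.zeros_like(h)
        for ((a1, a2), (b1, b2)), w in classes.items():
            if a1 != a2 and b1 != b2:
                w1 = h[a1, b1] * h[a2, b2]
                w2 = h[a1, b2] * h[a2, b1]
                tot = w1 + w2
                if tot <= 0:
                    w1 = w2 = 0.5
                    tot = 1.0
                exp[a1, b1] += w * w1 / tot; exp[a2, b2] += w * w1 / tot
                exp[a1, b2] += w * w2 / tot; exp[a2, b1] += w * w2 / tot
            else:
                exp[a1, b1] += w; exp[a2, b2] += w
        h = exp / exp.sum()
        cur = _class_loglik(h, classes)
        if abs(cur - prev) < tol:
            converged = True
            prev = cur
            break
        prev = cur
    return h, prev, converged


def _ld_statistic(genos, ka: int, kb: int) -> tuple[float, bool]:
    """LR statistic: EM haplotype model vs independence (product of allele
    frequencies)."""
    h, ll1, converged = _em_two_locus(genos, ka, kb)
    # null log-likelihood uses the product of the EM marginals
    h0 = np.outer(h.sum(axis=1), h.sum(axis=0))
    ll0 = _class_loglik(h0, _collapse(genos))
    return 2.0 * (ll1 - ll0), converged


def ld_test_females(genotypes_a: Sequence, genotypes_b: Sequence, *,
                    permutations: int = 1000, seed: int | None = None) -> TestResult:
    """Two-locus LD test for unphased female genotypes: likelihood-ratio
    statistic (EM haplotypes vs allele-frequency product), p-value by
    permuting one locus's genotypes across individuals."""
    if len(genotypes_a) != len(genotypes_b):
        raise ValueError("genotype vectors must be paired")
    pairs = [(a, b) for a, b in zip(genotypes_a, genotypes_b)
             if a is not None and b is not None]
    if len(pairs) < 2:
        raise ValueError("at least two complete individuals required")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if seed is None:
        raise ValueError("permutation test requires an explicit seed")
    amap = {a: i for i, a in enumerate(sorted({x for g, _ in pairs for x in g}))}
    bmap = {b: i for i, b in enumerate(sorted({x for _, g in pairs for x in g}))}
    ka, kb = len(amap), len(bmap)
    if ka < 2 or kb < 2:
        return TestResult(1.0, "degenerate", flags=("degenerate",))
    genos = [((amap[g1[0]], amap[g1[1]]), (bmap[g2[0]], bmap[g2[1]])) for g1, g2 in pairs]
    obs, converged = _ld_statistic(genos, ka, kb)
    flags = () if converged else ("em-max-iter",)

    rng = np.random.default_rng(seed)
    bgeno = [g[1] for g in genos]
    ageno = [g[0] for g in genos]
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(len(bgeno))
        shuffled = [(ageno[i], bgeno[perm[i]]) for i in range(len(bgeno))]
        stat, _ = _ld_statistic(shuffled, ka, kb)
        if stat >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    se = math.sqrt(p * (1 - p) / permutations)
    return TestResult(p, "permutation", se=se, steps=permutations, seed=seed,
                      statistic=obs, flags=flags)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

@dataclass
class BonferroniResult:
    threshold: float
    flags: list[bool]
    alpha: float
    m: int


def bonferroni(p_values: Sequence[float], alpha: float = 0.05,
               m: int | None = None) -> BonferroniResult:
    """Strict Bonferroni rule: significant iff p < alpha / m."""
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    return BonferroniResult(threshold, [p < threshold for p in p_values], alpha, m)
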