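"""Between-population statistics: pairwise Fst on chromosome-level allele
counts (haploid variance components) with permutation significance, and
Nei's unbiased genetic distance.

Fst uses the haploid AMOVA decomposition: for each allele, mean squares
among and within populations give variance components sigma2_a and sigma2_w;
summing components over alleles (and, for the multi-locus value, over loci)
yields Fst = sigma2_a / (sigma2_a + sigma2_w).  Each male contributes one
chromosome and each female two, so the unit of permutation is the
chromosome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np

from .io_formats import DistanceMatrix

# population -> locus -> allele -> chromosome count
PopCounts = Mapping[str, Mapping[str, Mapping[Hashable, int]]]


def _freq_matrix(counts_by_pop: Sequence[Mapping[Hashable, int]]):
    """Stack per-population allele counts over the union of alleles."""
    alleles = sorted({a for c in counts_by_pop for a in c})
    mat = np.array([[c.get(a, 0) for a in alleles] for c in counts_by_pop], dtype=float)
    return alleles, mat


def _variance_components(count_mat: np.ndarray) -> tuple[float, float]:
    """(sigma2_among, sigma2_within) for one locus from an (r pops x k
    alleles) chromosome-count matrix, summed over alleles."""
    sizes = count_mat.sum(axis=1)
    keep = sizes > 0
    count_mat = count_mat[keep]
    sizes = sizes[keep]
    r = len(sizes)
    if r < 2:
        raise ValueError("need at least two populations with data")
    n = sizes.sum()
    p = count_mat / sizes[:, None]
    pbar = count_mat.sum(axis=0) / n
    msp = (sizes[:, None] * (p - pbar) ** 2).sum() / (r - 1)
    msg = (sizes[:, None] * p * (1 - p)).sum() / (n - r)
    n_c = (n - (sizes ** 2).sum() / n) / (r - 1)
    sigma_a = (msp - msg) / n_c
    return float(sigma_a), float(msg)


@dataclass
class FstResult:
    labels: list[str]
    per_locus: dict[tuple[str, str], dict[str, float]]
    multi_locus: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)
    p_per_locus: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    permutations: int = 0
    seed: int | None = None

    def pair(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if (a, b) in self.multi_locus else (b, a)

    def to_distance_matrix(self, mode: str = "multilocus",
                           floor_negative: bool = True) -> DistanceMatrix:
        """Export as a distance matrix; ``mode`` is ``multilocus`` (variance
        -component ratio over all loci) or ``locus_mean`` (plain average of
        per-locus Fst).  Negative values are floored at 0 by default so the
        result is usable as a dissimilarity."""
        n = len(self.labels)
        m = np.zeros((n, n))
        for i, a in enumerate(self.labels):
            for j in range(i + 1, n):
                b = self.labels[j]
                key = self.pair(a, b)
                if mode == "multilocus":
                    v = self.multi_locus[key]
                elif mode == "locus_mean":
                    vals = list(self.per_locus[key].values())
                    v = float(np.mean(vals))
                else:
                    raise ValueError(f"unknown mode {mode!r}")
                if floor_negative:
                    v = max(v, 0.0)
                m[i, j] = m[j, i] = v
        return DistanceMatrix(list(self.labels), m)


def _pair_fst(counts_a: Mapping[str, Mapping], counts_b: Mapping[str, Mapping],
              loci: Sequence[str]) -> tuple[dict[str, float], float, dict[str, tuple[float, float]]]:
    per_locus: dict[str, float] = {}
    comps: dict[str, tuple[float, float]] = {}
    num = den = 0.0
    for locus in loci:
        _, mat = _freq_matrix([counts_a.get(locus, {}), counts_b.get(locus, {})])
        if mat.sum() == 0 or (mat.sum(axis=1) > 0).sum() < 2:
            continue
        sa, sw = _variance_components(mat)
        comps[locus] = (sa, sw)
        tot = sa + sw
        per_locus[locus] = sa / tot if tot > 0 else 0.0
        num += sa
        den += tot
    if not per_locus:
        raise ValueError("no locus with chromosomes in both populations")
    return per_locus, (num / den if den > 0 else 0.0), comps


def pairwise_fst(counts: PopCounts, *, permutations: int = 0,
                 seed: int | None = None) -> FstResult:
    """Per-locus and multi-locus Fst for every population pair.

    With ``permutations`` > 0 (seed required), chromosomes are relabelled
    across the two populations of each pair — independently per locus, since
    chromosome phase across loci is unknown for females — and the p-value is
    the fraction of replicates with Fst >= the observed value.
    """
    pops = list(counts)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for pop in pops:
        if sum(sum(c.values()) for c in counts[pop].values()) == 0:
            raise ValueError(f"population {pop!r} has no chromosomes at any locus")
    loci = sorted({l for pop in pops for l in counts[pop]})
    if permutations < 0 or (permutations and seed is None):
        raise ValueError("permutation test requires permutations >= 1 and a seed")

    rng = np.random.default_rng(seed) if permutations else None
    per_locus: dict[tuple[str, str], dict[str, float]] = {}
    multi: dict[tuple[str, str], float] = {}
    p_values: dict[tuple[str, str], float] = {}
    p_per_locus: dict[tuple[str, str], dict[str, float]] = {}

    for a, b in combinations(pops, 2):
        pl, ml, _ = _pair_fst(counts[a], counts[b], loci)
        per_locus[(a, b)] = pl
        multi[(a, b)] = ml
        if permutations:
            hits_ml = 0
            hits_pl = {l: 0 for l in pl}
            # pooled allele vectors and split sizes per locus
            pooled = {}
            for locus in pl:
                al_a, mat = _freq_matrix([counts[a].get(locus, {}), counts[b].get(locus, {})])
                na = int(mat[0].sum())
                vec = np.repeat(np.arange(mat.shape[1]), mat.sum(axis=0).astype(int))
                pooled[locus] = (vec, na, len(al_a))
            for _ in range(permutations):
                num = den = 0.0
                for locus, (vec, na, k) in pooled.items():
                    perm = rng.permutation(vec)
                    ca = np.bincount(perm[:na], minlength=k).astype(float)
                    cb = np.bincount(perm[na:], minlength=k).astype(float)
                    sa, sw = _variance_components(np.vstack([ca, cb]))
                    tot = sa + sw
                    fst_l = sa / tot if tot > 0 else 0.0
                    if fst_l >= pl[locus] - 1e-12:
                        hits_pl[locus] += 1
                    num += sa
                    den += tot
                if (num / den if den > 0 else 0.0) >= ml - 1e-12:
                    hits_ml += 1
            p_values[(a, b)] = (hits_ml + 1) / (permutations + 1)
            p_per_locus[(a, b)] = {l: (h + 1) / (permutations + 1) for l, h in hits_pl.items()}

    return FstResult(pops, per_locus, multi, p_values, p_per_locus, permutations, seed)


# ---------------------------------------------------------------------------
# Nei's unbiased genetic distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeiResult:
    d: float
    jx: float
    jy: float
    jxy: float
    infinite: bool


def nei_unbiased_distance(freqs_x: Sequence[Sequence[float]],
                          freqs_y: Sequence[Sequence[float]],
                          n_x: int | None = None, n_y: int | None = None,
                          *, bias_correction: bool = True) -> NeiResult:
    """Nei's genetic distance ``D = -ln(Jxy / sqrt(Jx * Jy))`` from per-locus
    frequency vectors over a shared allele order.

    ``Jx``, ``Jy``, ``Jxy`` are arithmetic means over loci of the gene
    identities.  With *bias_correction*, within-population identities use
    the unbiased haploid form ``(n * sum p^2 - 1) / (n - 1)`` (requires the
    chromosome sample sizes); small negative D values are then possible and
    are preserved.  Disjoint allele sets give +inf with a flag.
    """
    if len(freqs_x) != len(freqs_y):
        raise ValueError("need the same loci for both populations")
    if bias_correction and (n_x is None or n_y is None):
        raise ValueError("bias correction requires chromosome sample sizes")
    jx_terms, jy_terms, jxy_terms = [], [], []
    for fx, fy in zip(freqs_x, freqs_y):
        x = np.asarray(list(fx), dtype=float)
        y = np.asarray(list(fy), dtype=float)
        if x.shape != y.shape:
            raise ValueError("frequency vectors must share the allele order")
        sx = float((x ** 2).sum())
        sy = float((y ** 2).sum())
        if bias_correction:
            sx = (n_x * sx - 1.0) / (n_x - 1.0)
            sy = (n_y * sy - 1.0) / (n_y - 1.0)
        jx_terms.append(sx)
        jy_terms.append(sy)
        jxy_terms.append(float((x * y).sum()))
    jx = float(np.mean(jx_terms))
    jy = float(np.mean(jy_terms))
    jxy = float(np.mean(jxy_terms))
    if jxy <= 0.0:
        return NeiResult(math.inf, jx, jy, jxy, True)
    d = -math.log(jxy / math.sqrt(jx * jy))
    return NeiResult(d, jx, jy, jxy, False)


def nei_distance_matrix(freqs: Mapping[str, Sequence[Sequence[float]]],
                        sizes: Mapping[str, int] | None = None,
                        *, bias_correction: bool = True) -> DistanceMatrix:
    """Pairwise Nei distances between populations given per-locus frequency
    vectors on a common allele order per locus."""
    labels = list(freqs)
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            res = nei_unbiased_distance(
                freqs[a], freqs[b],
                sizes[a] if sizes else None, sizes[b] if sizes else None,
                bias_correction=bias_correction)
            m[i, j] = m[j, i] = res.d
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# significance summaries
# ---------------------------------------------------------------------------

@dataclass
class SignificanceMatrix:
    labels: list[str]
    flags: dict[tuple[str, str], dict[str, bool]]
    counts: dict[tuple[str, str], int]
    threshold: float


def fst_significance_matrix(result: FstResult, alpha: float = 0.05,
                            mode: str = "raw") -> SignificanceMatrix:
    """Per-locus significance flags for each population pair from the
    permutation p-values; ``mode='bonferroni'`` divides alpha by the number
    of loci tested per pair."""
    if not result.p_per_locus:
        raise ValueError("FstResult carries no permutation p-values")
    flags: dict[tuple[str, str], dict[str, bool]] = {}
    counts: dict[tuple[str, str], int] = {}
    threshold = alpha
    for pair, pvals in result.p_per_locus.items():
        m = len(pvals) if mode == "bonferroni" else 1
        threshold = alpha / m
        f = {locus: (p < threshold) for locus, p in pvals.items()}
        flags[pair] = f
        counts[pair] = sum(f.values())
    return SignificanceMatrix(result.labels, flags, counts, threshold)
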