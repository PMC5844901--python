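"""Export to the STRUCTURE input format and Evanno delta-K post-processing
of run log-likelihoods.  The admixture MCMC itself is external.

Export convention for mixed-ploidy X data: every individual gets two rows
(one allele per cell); a male's second row is filled with the missing code.
Microvariant alleles are recoded to unique integers as
``10 * repeat + variant digit`` so numeric order is preserved; the code map
is returned (and written) alongside the matrix.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np

from .io_formats import AlleleLabel, GenotypeTable

MISSING_CODE = -9


def allele_code(a: AlleleLabel) -> int:
    if a.variant > 9:
        raise ValueError(f"cannot recode microvariant {a} (variant digit > 9)")
    return 10 * a.repeat + a.variant


def build_recode_map(table: GenotypeTable) -> dict[str, dict[AlleleLabel, int]]:
    """Per-locus allele -> integer code map over the observed alleles."""
    out: dict[str, dict[AlleleLabel, int]] = {}
    for locus in table.loci:
        alleles = sorted({a for ind in table.individuals
                          for a in (ind.genotypes.get(locus) or ())})
        codes = {a: allele_code(a) for a in alleles}
        if len(set(codes.values())) != len(codes):
            raise ValueError(f"allele code collision at {locus}")
        out[locus] = codes
    return out


def export_structure_input(table: GenotypeTable, *, missing: int = MISSING_CODE,
                           dest: str | Path | TextIO | None = None,
                           ) -> tuple[str, dict[str, dict[AlleleLabel, int]]]:
    """Serialize a genotype table as STRUCTURE main input (two rows per
    individual, one allele per row and locus).  Returns (text, recode map)."""
    recode = build_recode_map(table)
    pops = {p: i + 1 for i, p in enumerate(table.populations)}
    buf = io.StringIO()
    buf.write("\t".join(table.loci) + "\n")
    for ind in table.individuals:
        rows: list[list[int]] = [[], []]
        for locus in table.loci:
            g = ind.genotypes.get(locus)
            if g is None:
                rows[0].append(missing)
                rows[1].append(missing)
            elif len(g) == 1:  # male: one X copy, second row missing
                rows[0].append(recode[locus][g[0]])
                rows[1].append(missing)
            else:
                a, b = sorted(g)
                rows[0].append(recode[locus][a])
                rows[1].append(recode[locus][b])
        for row in rows:
            buf.write("\t".join([ind.sample_id, str(pops[ind.population])]
                                + [str(x) for x in row]) + "\n")
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text, encoding="utf-8")
        else:
            dest.write(text)
    return text, recode


def read_structure_counts(text: str, *, missing: int = MISSING_CODE) -> dict[str, dict[int, int]]:
    """Re-import an exported file; per-locus counts of non-missing allele
    codes (used for round-trip verification)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    loci = lines[0].split("\t")
    counts: dict[str, dict[int, int]] = {l: {} for l in loci}
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(loci) + 2:
            raise ValueError(f"malformed STRUCTURE row: {ln!r}")
        for locus, cell in zip(loci, parts[2:]):
            code = int(cell)
            if code == missing:
                continue
            counts[locus][code] = counts[locus].get(code, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class EvannoRow:
    k: int
    reps: int
    mean_l: float
    sd_l: float
    l_prime: float | None  # mean L(K) - mean L(K-1)
    l_second: float | None  # |mean L(K+1) - 2 mean L(K) + mean L(K-1)|
    delta_k: float | None
    flags: tuple[str, ...] = ()


@dataclass
class EvannoTable:
    rows: list[EvannoRow]
    best_k: int | None

    def row(self, k: int) -> EvannoRow:
        for r in self.rows:
            if r.k == k:
                return r
        raise KeyError(k)


def evanno_delta_k(runs: Mapping[int, Sequence[float]]) -> EvannoTable:
    """Evanno second-difference statistic over replicate STRUCTURE
    log-likelihoods: delta K = |L''(K)| / sd(L(K)); the most likely K is the
    argmax over interior K values with positive replicate spread."""
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    means = {k: float(np.mean(runs[k])) for k in ks}
    sds = {k: float(np.std(runs[k], ddof=1)) if len(runs[k]) > 1 else 0.0 for k in ks}
    rows: list[EvannoRow] = []
    for k in ks:
        interior = ks[0] < k < ks[-1]
        l_prime = means[k] - means[k - 1] if k > ks[0] else None
        l_second = abs(means[k + 1] - 2 * means[k] + means[k - 1]) if interior else None
        flags: tuple[str, ...] = ()
        delta = None
        if interior:
            if len(runs[k]) < 2:
                raise ValueError(f"interior K={k} needs >= 2 replicates")
            if sds[k] > 0:
                delta = l_second / sds[k]
            else:
                flags = ("sd-zero",)
        rows.append(EvannoRow(k, len(runs[k]), means[k], sds[k], l_prime,
                              l_second, delta, flags))
    candidates = [(r.delta_k, r.k) for r in rows if r.delta_k is not None]
    best_k = max(candidates)[1] if candidates else None
    return EvannoTable(rows, best_k)


def evanno_csv(table: EvannoTable) -> str:
    """CSV rendering: K, reps, meanL, sd, L', |L''|, deltaK."""
    def fmt(x):
        return "" if x is None else f"{x:.6g}"
    lines = ["K,reps,mean_L,sd_L,L_prime,L_second_abs,delta_K"]
    for r in table.rows:
        lines.append(",".join([str(r.k), str(r.reps), f"{r.mean_l:.6g}",
                               f"{r.sd_l:.6g}", fmt(r.l_prime), fmt(r.l_second),
                               fmt(r.delta_k)]))
    return "\n".join(lines) + "\n"
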