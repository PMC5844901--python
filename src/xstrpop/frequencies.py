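"""Allele and haplotype counting with X-chromosome dosage.

Each male contributes one chromosome per locus, each female two.  Missing
genotypes are dropped per locus (an individual missing locus L is excluded
only from L's counts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import AlleleLabel, GenotypeTable, LinkageGroupDef


@dataclass
class FrequencyEntry:
    """Allele counts and frequencies for one locus in one population slice."""

    locus: str
    population: str | None
    counts: dict[AlleleLabel, int]
    n_chrom: int
    frequencies: dict[AlleleLabel, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_chrom != sum(self.counts.values()):
            raise ValueError("n_chrom does not match the sum of counts")
        ordered = sorted(self.counts)
        self.counts = {a: self.counts[a] for a in ordered}
        self.frequencies = {a: self.counts[a] / self.n_chrom for a in ordered}

    @property
    def freq_vector(self) -> list[float]:
        return list(self.frequencies.values())


def allele_counts(table: GenotypeTable, locus: str, *, population: str | None = None,
                  sex: str = "pooled") -> Counter[AlleleLabel]:
    """Chromosome-dose allele counts (male 1, female 2) at *locus*.

    ``sex`` is ``'M'``, ``'F'`` or ``'pooled'``.  An empty selection yields
    an empty mapping, not an error.
    """
    if locus not in table.loci:
        raise KeyError(f"unknown locus {locus!r}")
    if sex not in ("M", "F", "pooled"):
        raise ValueError(f"sex filter must be M, F or pooled, not {sex!r}")
    counts: Counter[AlleleLabel] = Counter()
    for ind in table.individuals:
        if population is not None and ind.population != population:
            continue
        if sex != "pooled" and ind.sex != sex:
            continue
        g = ind.genotypes.get(locus)
        if g is None:
            continue
        counts.update(g)
    return counts


def allele_frequencies(counts: Mapping[AlleleLabel, int], *, locus: str = "",
                       population: str | None = None) -> FrequencyEntry:
    """Normalize counts into a :class:`FrequencyEntry`; frequencies sum to 1
    and are kept in allele order."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("cannot compute frequencies with zero chromosomes")
    return FrequencyEntry(locus, population, dict(counts), n)


def frequency_table(table: GenotypeTable, *, sex: str = "pooled") -> list[FrequencyEntry]:
    """Per (locus, population) frequency entries for a whole genotype table."""
    out = []
    for pop in table.populations:
        for locus in table.loci:
            counts = allele_counts(table, locus, population=pop, sex=sex)
            if counts:
                out.append(allele_frequencies(counts, locus=locus, population=pop))
    return out


@dataclass
class HaplotypeTable:
    """Male haplotype counts for one linkage group."""

    group: LinkageGroupDef
    counts: dict[tuple[AlleleLabel, ...], int]
    n_males: int  # males with complete data for the group

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_males:
            raise ValueError("haplotype counts do not sum to n_males")

    @property
    def frequencies(self) -> dict[tuple[AlleleLabel, ...], float]:
        return {h: c / self.n_males for h, c in self.counts.items()}

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def most_common(self) -> tuple[tuple[AlleleLabel, ...], int]:
        return max(self.counts.items(), key=lambda kv: (kv[1], kv[0]))


def haplotype_counts(table: GenotypeTable, lg: LinkageGroupDef) -> HaplotypeTable:
    """Count male three-locus haplotypes; males with any missing locus in the
    triple are excluded from that group's sample size."""
    for locus in lg.loci:
        if locus not in table.loci:
            raise KeyError(f"locus {locus!r} of {lg.name} not in table")
    counts: Counter[tuple[AlleleLabel, ...]] = Counter()
    n = 0
    for ind in table.individuals:
        if ind.sex != "M":
            raise ValueError(
                f"haplotype counting requires males only; {ind.sample_id!r} is female"
            )
        gs = [ind.genotypes.get(l) for l in lg.loci]
        if any(g is None for g in gs):
            continue
        counts[tuple(g[0] for g in gs)] += 1  # type: ignore[index]
        n += 1
    return HaplotypeTable(lg, dict(counts), n)


@dataclass
class DiversityResult:
    hd: float
    n: int
    sum_p2: float


def haplotype_diversity(counts: Mapping, n: int | None = None) -> DiversityResult:
    """Unbiased haplotype diversity ``HD = n (1 - sum p^2) / (n - 1)``.

    *counts* may be a :class:`HaplotypeTable` or a mapping haplotype -> count.
    """
    if isinstance(counts, HaplotypeTable):
        mapping = counts.counts
        n = counts.n_males
    else:
        mapping = dict(counts)
        if n is None:
            n = sum(mapping.values())
        elif n != sum(mapping.values()):
            raise ValueError("n does not match the sum of counts")
    if n < 2:
        raise ValueError("haplotype diversity requires at least 2 observations")
    sum_p2 = sum((c / n) ** 2 for c in mapping.values())
    hd = n * (1.0 - sum_p2) / (n - 1)
    return DiversityResult(hd=hd, n=n, sum_p2=sum_p2)


def haplotype_csv_rows(h: HaplotypeTable) -> Iterable[tuple[str, str, int, float]]:
    """(group, haplotype, count, frequency) rows, most common first."""
    freqs = h.frequencies
    for hap, count in sorted(h.counts.items(), key=lambda kv: (-kv[1], kv[0])):
        label = "-".join(str(a) for a in hap)
        yield (h.group.name, label, count, freqs[hap])
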