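"""Synthetic X-linked STR data with known ground truth.

Generators cover: Dirichlet allele frequencies, single populations with an
optional inbreeding-style HWE distortion F (female homozygote probability
``p^2 + F p (1-p)``), male three-locus haplotype structure for linkage
groups, and multi-population divergence under the Balding-Nichols model
(per-population frequencies drawn from ``Dirichlet(p (1-Fst)/Fst)``).

Every generator is a pure function of its arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_formats import AlleleLabel, GenotypeTable, Individual, LinkageGroupDef


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    return np.random.default_rng(seed)


def default_allele_labels(k: int, start: int = 8) -> list[AlleleLabel]:
    return [AlleleLabel(start + i) for i in range(k)]


@dataclass
class SimulationConfig:
    """Declarative spec for a multi-population X-STR dataset."""

    seed: int
    loci: dict[str, int]  # locus name -> allele count
    sizes: list[tuple[int, int]]  # per population: (n_males, n_females)
    concentration: float = 1.0
    hwe_f: float = 0.0
    fst: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("target Fst must be in [0, 1)")
        if not (0.0 <= self.hwe_f <= 1.0):
            raise ValueError("HWE distortion F must be in [0, 1]")
        if any(nm < 0 or nf < 0 for nm, nf in self.sizes):
            raise ValueError("sample sizes must be >= 0")

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        data = yaml.safe_load(text)
        data["sizes"] = [tuple(x) for x in data["sizes"]]
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "seed": self.seed, "loci": dict(self.loci),
            "sizes": [list(x) for x in self.sizes],
            "concentration": self.concentration,
            "hwe_f": self.hwe_f, "fst": self.fst,
        }, sort_keys=False)


def paper_like_config(seed: int) -> SimulationConfig:
    """Two populations with the study's sample sizes and 12 loci of 8-25
    alleles."""
    rng = np.random.default_rng(seed)
    loci = {f"LOC{i + 1:02d}": int(rng.integers(8, 26)) for i in range(12)}
    return SimulationConfig(seed=seed, loci=loci, sizes=[(116, 116), (200, 109)])


def simulate_frequencies(k: int, concentration: float = 1.0,
                         seed=None) -> np.ndarray:
    """One Dirichlet(concentration) frequency vector of length k."""
    if k < 1:
        raise ValueError("need at least one allele")
    if k == 1:
        return np.array([1.0])
    rng = _rng(seed)
    return rng.dirichlet(np.full(k, concentration))


def _sample_female(freqs: np.ndarray, f: float, rng: np.random.Generator) -> tuple[int, int]:
    # hom prob p^2 + F p (1-p); het prob (1-F) 2 p_i p_j
    if f > 0 and rng.random() < f:
        a = rng.choice(len(freqs), p=freqs)
        return (int(a), int(a))
    a, b = rng.choice(len(freqs), size=2, p=freqs)
    return (int(a), int(b))


def simulate_population(freqs: Mapping[str, Sequence[float]], n_males: int,
                        n_females: int, *, hwe_f: float = 0.0, seed=None,
                        population: str = "pop1",
                        alleles: Mapping[str, Sequence[AlleleLabel]] | None = None,
                        id_prefix: str = "") -> GenotypeTable:
    """Sample a single population: hemizygous males, diploid females with
    optional HWE distortion F in [0, 1]."""
    if not (0.0 <= hwe_f <= 1.0):
        raise ValueError("F must be in [0, 1]")
    rng = _rng(seed)
    loci = list(freqs)
    labels = {l: (list(alleles[l]) if alleles else default_allele_labels(len(freqs[l])))
              for l in loci}
    for l in loci:
        if len(labels[l]) != len(list(freqs[l])):
            raise ValueError(f"allele labels do not match frequencies at {l}")
    inds: list[Individual] = []
    for i in range(n_males):
        g = {}
        for l in loci:
            p = np.asarray(list(freqs[l]), dtype=float)
            a = int(rng.choice(len(p), p=p))
            g[l] = (labels[l][a],)
        inds.append(Individual(f"{id_prefix}{population}_M{i + 1:04d}", "M", population, g))
    for i in range(n_females):
        g = {}
        for l in loci:
            p = np.asarray(list(freqs[l]), dtype=float)
            a, b = _sample_female(p, hwe_f, rng)
            g[l] = (labels[l][a], labels[l][b])
        inds.append(Individual(f"{id_prefix}{population}_F{i + 1:04d}", "F", population, g))
    return GenotypeTable(loci, inds)


def simulate_linked_males(haplotypes: Mapping[tuple[AlleleLabel, ...], float],
                          lg: LinkageGroupDef, n_males: int, *, seed=None,
                          population: str = "pop1") -> GenotypeTable:
    """Draw male three-locus haplotypes i.i.d. from the given haplotype
    frequency spectrum."""
    if not haplotypes:
        raise ValueError("empty haplotype set")
    haps = list(haplotypes)
    probs = np.array([haplotypes[h] for h in haps], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    if any(len(h) != len(lg.loci) for h in haps):
        raise ValueError("haplotype length does not match the linkage group")
    rng = _rng(seed)
    inds = []
    draws = rng.choice(len(haps), size=n_males, p=probs)
    for i, hidx in enumerate(draws):
        hap = haps[int(hidx)]
        g = {locus: (allele,) for locus, allele in zip(lg.loci, hap)}
        inds.append(Individual(f"{population}_M{i + 1:04d}", "M", population, g))
    return GenotypeTable(list(lg.loci), inds)


def balding_nichols_frequencies(ancestral: Sequence[float], fst: float,
                                n_pops: int, *, seed=None) -> list[np.ndarray]:
    """Per-population frequency vectors at the target divergence."""
    p = np.asarray(list(ancestral), dtype=float)
    if not (0.0 <= fst < 1.0):
        raise ValueError("target Fst must be in [0, 1)")
    rng = _rng(seed)
    if fst == 0.0:
        return [p.copy() for _ in range(n_pops)]
    conc = p * (1.0 - fst) / fst
    return [rng.dirichlet(conc) for _ in range(n_pops)]


def simulate_divergent_populations(ancestral: Mapping[str, Sequence[float]],
                                   fst: float, n_pops: int,
                                   sizes: Sequence[tuple[int, int]], *,
                                   hwe_f: float = 0.0, seed=None,
                                   alleles: Mapping[str, Sequence[AlleleLabel]] | None = None,
                                   ) -> GenotypeTable:
    """Balding-Nichols divergence at the target Fst, then per-population
    genotype sampling.  Population labels are pop1..popN."""
    if len(sizes) != n_pops:
        raise ValueError("need one (n_males, n_females) pair per population")
    rng = _rng(seed)
    loci = list(ancestral)
    pop_freqs: list[dict[str, np.ndarray]] = [dict() for _ in range(n_pops)]
    for l in loci:
        per_pop = balding_nichols_frequencies(ancestral[l], fst, n_pops, seed=rng)
        for i in range(n_pops):
            pop_freqs[i][l] = per_pop[i]
    tables = []
    for i, (nm, nf) in enumerate(sizes):
        tables.append(simulate_population(pop_freqs[i], nm, nf, hwe_f=hwe_f,
                                          seed=rng, population=f"pop{i + 1}",
                                          alleles=alleles))
    inds = [ind for t in tables for ind in t.individuals]
    return GenotypeTable(loci, inds)


def simulate_dataset(config: SimulationConfig) -> GenotypeTable:
    """End-to-end: draw ancestral frequencies per locus, then divergent
    populations per the config."""
    rng = np.random.default_rng(config.seed)
    ancestral = {l: simulate_frequencies(k, config.concentration, seed=rng)
                 for l, k in config.loci.items()}
    return simulate_divergent_populations(ancestral, config.fst, len(config.sizes),
                                          config.sizes, hwe_f=config.hwe_f, seed=rng)
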