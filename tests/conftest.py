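import io

import numpy as np
import pytest

from xstrpop.io_formats import (
    AlleleLabel, GenotypeTable, Individual, LinkageGroupDef,
)


def A(text: str) -> AlleleLabel:
    return AlleleLabel.parse(str(text))


@pytest.fixture
def toy_table() -> GenotypeTable:
    """Two loci, one male + two females in one population."""
    return GenotypeTable(
        ["L1", "L2"],
        [
            Individual("m1", "M", "popA", {"L1": (A(8),), "L2": (A(12),)}),
            Individual("f1", "F", "popA", {"L1": (A(8), A(9)), "L2": (A(12), A(13))}),
            Individual("f2", "F", "popA", {"L1": (A(9), A(9)), "L2": None}),
        ],
    )


@pytest.fixture
def canonical_tsv() -> str:
    return (
        "sample\tsex\tpopulation\tL1\tL2\n"
        "m1\tM\tpopA\t8\t12\n"
        "f1\tF\tpopA\t8/9\t12/13\n"
        "f2\tF\tpopA\t9/9\t.\n"
    )


@pytest.fixture
def lg3() -> LinkageGroupDef:
    return LinkageGroupDef("LG3", ("DXS10101", "DXS10103", "HPRTB"))


def male_table(haps, loci=("X1", "X2", "X3"), population="popA") -> GenotypeTable:
    """Build an all-male table from a list of allele-label triples."""
    inds = [
        Individual(f"m{i}", "M", population,
                   {l: ((A(a),) if a is not None else None)
                    for l, a in zip(loci, hap)})
        for i, hap in enumerate(haps)
    ]
    return GenotypeTable(list(loci), inds)


def female_genotype_counts(table: GenotypeTable, locus: str) -> dict:
    out: dict = {}
    for ind in table.individuals:
        if ind.sex != "F":
            continue
        g = ind.genotypes.get(locus)
        if g is None:
            continue
        key = tuple(sorted(g))
        out[key] = out.get(key, 0) + 1
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
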