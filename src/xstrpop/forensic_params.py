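"""Per-locus forensic efficiency statistics from allele frequencies, and
multi-locus combined parameters.

All closed forms are polynomial in the frequency power sums
``a_r = sum_i p_i^r``:

==================  =====================================================
HOM                 a2
HET                 1 - a2
PIC                 1 - a2 - a2^2 + a4
PD_M                1 - a2           (two random male genotypes differ)
PD_F                1 - 2 a2^2 + a4  (two random female genotypes differ)
PE                  HET^2 (1 - 2 HET HOM^2)   (heterozygosity-based
                    approximation of trio exclusion, the PowerStats form)
PI                  HOM / 2          (ChrX reporting convention)
MEC (Krueger)       1 - 2a2 + a3 + 2a4 - 3a5 - 2a2^2 + 3 a2 a3
                    = exact exclusion chance in an autosomal-style trio
                    (mother, child and alleged father all diploid)
MEC (Kishida)       trio with daughter, hemizygous alleged father,
                    computed as the explicit sum over mother/daughter
                    configurations; algebraically equal to PIC
MEC (Desmarais)     PIC              (same trio-with-daughter scenario)
MEC (duo)           1 - 2a2 + a3     (father/daughter or mother/son duo)
==================  =====================================================

The trio/duo exclusion forms were re-derived symbolically from the mating
scenarios under HWE and are validated against Monte Carlo exclusion
simulations in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

_FREQ_SUM_TOL = 1e-6


@dataclass(frozen=True)
class PowerSums:
    """Power sums of an allele frequency vector (a2..a5)."""

    s2: float
    s3: float
    s4: float
    s5: float


def power_sums(freqs: Sequence[float]) -> PowerSums:
    p = np.asarray(list(freqs), dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any():
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > _FREQ_SUM_TOL:
        raise ValueError(f"frequencies sum to {p.sum()!r}, not 1")
    return PowerSums(float((p ** 2).sum()), float((p ** 3).sum()),
                     float((p ** 4).sum()), float((p ** 5).sum()))


@dataclass(frozen=True)
class LocusForensicProfile:
    """The per-locus statistic battery (all in [0, 1] except PI >= 0)."""

    pic: float
    hom: float
    het: float
    pe: float
    pi: float
    pd_m: float
    pd_f: float
    mec_kruger: float
    mec_kishida: float
    mec_desmarais: float
    mec_desmarais_duo: float

    #: report column order
    FIELDS = ("pic", "hom", "het", "pe", "pi", "pd_f", "pd_m",
              "mec_kruger", "mec_kishida", "mec_desmarais", "mec_desmarais_duo")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS}


def _mec_kishida(p: np.ndarray) -> float:
    """Mean exclusion chance for a mother/daughter/alleged-father trio with a
    hemizygous father, as the direct sum over mother genotypes and paternal
    alleles.  Equals PIC analytically; kept as an independent route."""
    k = p.size
    total = 0.0
    # loop over (mother genotype, transmitted maternal allele, paternal allele)
    for i in range(k):
        for j in range(i, k):
            geno_p = p[i] * p[j] * (2.0 if i != j else 1.0)
            maternal = ((i, 0.5), (j, 0.5)) if i != j else ((i, 1.0),)
            for m, w in maternal:
                for f in range(k):
                    # daughter = {m, f}; obligate paternal alleles given the
                    # mother's genotype {i, j}
                    daughter = (min(m, f), max(m, f))
                    obligate = set()
                    for mm in {i, j}:
                        a, b = daughter
                        if mm == a:
                            obligate.add(b)
                        if mm == b:
                            obligate.add(a)
                    excl = 1.0 - sum(p[s] for s in obligate)
                    total += geno_p * w * p[f] * excl
    return total


def forensic_profile(freqs: Sequence[float]) -> LocusForensicProfile:
    """Compute the full statistic battery from one locus's (pooled) allele
    frequencies.  A single-allele locus yields zero discrimination and
    exclusion power with PI = 0.5."""
    p = np.asarray(list(freqs), dtype=float)
    s = power_sums(p)
    a2, a3, a4, a5 = s.s2, s.s3, s.s4, s.s5
    hom = a2
    het = 1.0 - a2
    pic = 1.0 - a2 - a2 * a2 + a4
    pd_m = het
    pd_f = 1.0 - 2.0 * a2 * a2 + a4
    pe = het * het * (1.0 - 2.0 * het * hom * hom)
    pi = hom / 2.0
    mec_kruger = 1.0 - 2.0 * a2 + a3 + 2.0 * a4 - 3.0 * a5 - 2.0 * a2 * a2 + 3.0 * a2 * a3
    mec_kishida = _mec_kishida(p)
    mec_desmarais = pic
    mec_duo = 1.0 - 2.0 * a2 + a3
    return LocusForensicProfile(
        pic=pic, hom=hom, het=het, pe=pe, pi=pi, pd_m=pd_m, pd_f=pd_f,
        mec_kruger=mec_kruger, mec_kishida=mec_kishida,
        mec_desmarais=mec_desmarais, mec_desmarais_duo=mec_duo,
    )


def combined_parameter(values: Iterable[float]) -> float:
    """``1 - prod(1 - x)`` over per-locus values, in log space so that
    complements far below 1e-12 do not underflow."""
    vals = list(values)
    if not vals:
        raise ValueError("at least one locus required")
    log_comp = 0.0
    for x in vals:
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"per-locus value {x} outside [0, 1]")
        if x == 1.0:
            return 1.0
        log_comp += math.log1p(-x)
    return -math.expm1(log_comp)


@dataclass(frozen=True)
class CombinedParameters:
    """Multi-locus combined statistics (each ``1 - prod(1 - x_l)``)."""

    cpd_f: float
    cpd_m: float
    cmec_duo: float
    cmec_trio: float


def combined_parameters(profiles: Mapping[str, LocusForensicProfile]) -> CombinedParameters:
    if not profiles:
        raise ValueError("at least one locus required")
    vals = list(profiles.values())
    return CombinedParameters(
        cpd_f=combined_parameter(p.pd_f for p in vals),
        cpd_m=combined_parameter(p.pd_m for p in vals),
        cmec_duo=combined_parameter(p.mec_desmarais_duo for p in vals),
        cmec_trio=combined_parameter(p.mec_desmarais for p in vals),
    )
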