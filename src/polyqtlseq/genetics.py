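"""Exact dosage genetics for autopolyploid crosses.

An autopolyploid carries ``ploidy`` homologous copies of each chromosome and an
allele may be present in any dosage from 0 (nulliplex) through 1 (simplex),
2 (duplex), ... up to ``ploidy``.  Under random bivalent pairing and no double
reduction, a gamete receives ``ploidy/2`` chromosomes drawn without replacement
from the parent's homologues, so the gamete dosage of an allele is
hypergeometric.  Everything here is computed in exact rational/integer
arithmetic; floats appear only at the caller's boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Literal, Mapping

__all__ = [
    "PloidyConfig",
    "DosageDistribution",
    "expected_snp_index",
    "gamete_dosage_distribution",
    "progeny_dosage_distribution",
    "combination_count",
]

CrossType = Literal["F1_outcross", "F2_diploid"]


def _check_ploidy(ploidy: int) -> int:
    if not isinstance(ploidy, int) or ploidy < 2 or ploidy % 2 != 0:
        raise ValueError(f"ploidy must be an even integer >= 2, got {ploidy!r}")
    return ploidy


def _check_dosage(ploidy: int, dosage: int, name: str = "dosage") -> int:
    if not isinstance(dosage, int) or not (0 <= dosage <= ploidy):
        raise ValueError(f"{name} must be an integer in [0, {ploidy}], got {dosage!r}")
    return dosage


@dataclass(frozen=True)
class PloidyConfig:
    """Ploidy level of the cross (4 for potato, 6 for sweetpotato)."""

    ploidy: int

    def __post_init__(self) -> None:
        _check_ploidy(self.ploidy)

    @property
    def gamete_size(self) -> int:
        return self.ploidy // 2


@dataclass(frozen=True)
class DosageDistribution:
    """Exact probability mass over allele dosages ``0..ploidy``.

    ``probabilities`` maps dosage -> Fraction; zero-mass dosages are omitted.
    """

    ploidy: int
    probabilities: Mapping[int, Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values(), start=Fraction(0))
        if total != 1:
            raise ValueError(f"probabilities sum to {total}, expected 1")
        if any(p < 0 for p in self.probabilities.values()):
            raise ValueError("negative probability mass")

    def mean(self) -> Fraction:
        return sum((k * p for k, p in self.probabilities.items()), start=Fraction(0))

    def as_floats(self) -> dict[int, float]:
        return {k: float(p) for k, p in self.probabilities.items()}

    def support(self) -> list[int]:
        return sorted(self.probabilities)


def expected_snp_index(ploidy: int, dosage: int) -> float:
    """Asymptotic SNP index of a dosage class: the allele fraction dosage/ploidy.

    For a tetraploid this gives 0.25 / 0.50 / 0.75 for simplex / duplex /
    triplex; for a hexaploid, 1/6 ~ 0.17 for simplex and so on.
    """
    _check_ploidy(ploidy)
    _check_dosage(ploidy, dosage)
    return float(Fraction(dosage, ploidy))


def gamete_dosage_distribution(ploidy: int, parent_dosage: int) -> DosageDistribution:
    """Dosage of an allele in a gamete of a parent carrying ``parent_dosage`` copies.

    ploidy/2 chromosomes are drawn without replacement from the parent's
    homologues (random bivalent pairing, no double reduction), so

        P(k) = C(d, k) * C(ploidy - d, g - k) / C(ploidy, g),   g = ploidy / 2.

    A simplex parent (d=1) transmits the allele to half its gametes, giving the
    1:1 simplex:nulliplex segregation used throughout polyploid mapping.
    """
    _check_ploidy(ploidy)
    _check_dosage(ploidy, parent_dosage, "parent_dosage")
    g = ploidy // 2
    denom = comb(ploidy, g)
    probs: dict[int, Fraction] = {}
    for k in range(0, g + 1):
        num = comb(parent_dosage, k) * comb(ploidy - parent_dosage, g - k)
        if num:
            probs[k] = Fraction(num, denom)
    return DosageDistribution(ploidy=ploidy, probabilities=probs)


def progeny_dosage_distribution(
    ploidy: int, p1_dosage: int, p2_dosage: int
) -> DosageDistribution:
    """Progeny dosage distribution: convolution of the two parents' gamete dosages.

    Simplex x nulliplex gives simplex:nulliplex = 1:1; simplex x simplex gives
    duplex:simplex:nulliplex = 1:2:1, independent of ploidy.
    """
    g1 = gamete_dosage_distribution(ploidy, p1_dosage)
    g2 = gamete_dosage_distribution(ploidy, p2_dosage)
    probs: dict[int, Fraction] = {}
    for k1, q1 in g1.probabilities.items():
        for k2, q2 in g2.probabilities.items():
            probs[k1 + k2] = probs.get(k1 + k2, Fraction(0)) + q1 * q2
    return DosageDistribution(ploidy=ploidy, probabilities=probs)


def combination_count(ploidy: int, n_chromosomes: int, cross_type: CrossType) -> int:
    """Exact number of distinct whole-genome chromosome combinations in the progeny.

    ``F1_outcross``: each parent contributes one of C(ploidy, ploidy/2)
    chromosome subsets per homologous group, so the count is
    (C(ploidy, ploidy/2)^2) ** n_chromosomes — 4.7e18 for a tetraploid with 12
    chromosomes and 1.1e39 for a hexaploid with 15.  ``F2_diploid``: the
    classical 3 ** n_chromosomes diploid F2 count (AA/AB/BB per chromosome),
    5.3e5 for 12 chromosomes.  Crossovers within chromosomes are ignored.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if cross_type == "F1_outcross":
        _check_ploidy(ploidy)
        per_chrom = comb(ploidy, ploidy // 2) ** 2
        return per_chrom**n_chromosomes
    if cross_type == "F2_diploid":
        if ploidy != 2:
            raise ValueError("F2_diploid counting is defined for ploidy 2 only")
        return 3**n_chromosomes
    raise ValueError(f"unknown cross_type {cross_type!r}")
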