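"""Read-depth design simulation for dosage-class discrimination.

At a site where an allele has dosage ``d`` out of ``ploidy`` homologues, the
observed SNP index at read depth ``n`` is Binomial(n, d/ploidy)/n.  These
simulations map how the index distributions of the simplex and duplex classes
separate as depth grows, and hence how deep one must sequence before simplex
SNPs can be extracted by an index window without duplex contamination.

The shipped presets (tetraploid: index 0.10-0.36 at depth >= 40; hexaploid:
0.08-0.25 at depth >= 75) are fixed defaults of the method, not quantities this
module re-derives; :func:`extraction_range` implements an explicit, reproducible
central-quantile criterion instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .genetics import _check_dosage, _check_ploidy

__all__ = [
    "DepthSimResult",
    "ExtractionRange",
    "PRESET_EXTRACTION_RANGES",
    "simulate_index_distribution",
    "extraction_range",
    "minimum_depth",
]


@dataclass(frozen=True)
class DepthSimResult:
    """Simulated SNP-index distribution for one (ploidy, dosage, depth) cell."""

    ploidy: int
    dosage: int
    depth: int
    n_reps: int
    seed: int
    indices: np.ndarray  # shape (n_reps,), values in [0, 1]

    def quantile(self, p: float | Sequence[float]) -> np.ndarray | float:
        """Empirical inverse-CDF quantile (lowest value with CDF >= p)."""
        return np.quantile(self.indices, p, method="inverted_cdf")

    def quantiles(self, probs: Iterable[float]) -> dict[float, float]:
        return {p: float(self.quantile(p)) for p in probs}

    def mean(self) -> float:
        return float(self.indices.mean())

    def fraction_within(self, lo: float, hi: float) -> float:
        """Fraction of replicates with index in the closed interval [lo, hi]."""
        return float(np.mean((self.indices >= lo) & (self.indices <= hi)))


@dataclass(frozen=True)
class ExtractionRange:
    """Closed SNP-index interval used to extract a dosage class."""

    lo: float
    hi: float
    depth: int
    confidence: float
    degenerate: bool = False  # True when the range collapsed to the full [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError(f"invalid range [{self.lo}, {self.hi}]")

    def contains(self, index: float | np.ndarray) -> np.ndarray | bool:
        return (index >= self.lo) & (index <= self.hi)


#: Fixed method defaults for simplex extraction (tetraploid at depth 40,
#: hexaploid at depth 75), shipped as presets rather than recomputed.
PRESET_EXTRACTION_RANGES: dict[int, ExtractionRange] = {
    4: ExtractionRange(lo=0.10, hi=0.36, depth=40, confidence=0.95),
    6: ExtractionRange(lo=0.08, hi=0.25, depth=75, confidence=0.95),
}


def simulate_index_distribution(
    ploidy: int,
    dosage: int,
    depth: int,
    n_reps: int,
    seed: int = 0,
) -> DepthSimResult:
    """Simulate observed SNP indices: Binomial(depth, dosage/ploidy) / depth."""
    _check_ploidy(ploidy)
    _check_dosage(ploidy, dosage)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    alt = rng.binomial(depth, dosage / ploidy, size=n_reps)
    return DepthSimResult(
        ploidy=ploidy,
        dosage=dosage,
        depth=depth,
        n_reps=n_reps,
        seed=seed,
        indices=alt / depth,
    )


def _central_interval(
    ploidy: int,
    depth: int,
    confidence: float,
    n_reps: int,
    seed: int,
    method: Literal["simulate", "exact"],
) -> tuple[float, float]:
    p_lo, p_hi = (1 - confidence) / 2, (1 + confidence) / 2
    if method == "exact":
        dist = stats.binom(depth, 1 / ploidy)
        return float(dist.ppf(p_lo) / depth), float(dist.ppf(p_hi) / depth)
    sim = simulate_index_distribution(ploidy, 1, depth, n_reps, seed)
    return float(sim.quantile(p_lo)), float(sim.quantile(p_hi))


def extraction_range(
    ploidy: int,
    depth: int,
    confidence: float = 0.95,
    n_reps: int = 10_000,
    seed: int = 0,
    method: Literal["simulate", "exact"] = "simulate",
) -> ExtractionRange:
    """Central ``confidence`` quantile interval of the simplex index at ``depth``.

    The interval always contains the asymptotic simplex index 1/ploidy.  When
    the depth is too small for any separation the full [0, 1] interval is
    returned with ``degenerate=True``.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    lo, hi = _central_interval(ploidy, depth, confidence, n_reps, seed, method)
    target = 1 / ploidy
    lo, hi = min(lo, target), max(hi, target)
    if lo <= 0.0 and hi >= 1.0:
        return ExtractionRange(0.0, 1.0, depth, confidence, degenerate=True)
    if lo == hi:  # depth 1 style collapse
        return ExtractionRange(0.0, 1.0, depth, confidence, degenerate=True)
    return ExtractionRange(lo, hi, depth, confidence)


def duplex_leakage(
    ploidy: int,
    depth: int,
    rng_range: ExtractionRange,
    n_reps: int = 0,
    seed: int = 0,
    method: Literal["simulate", "exact"] = "exact",
) -> float:
    """Probability that a duplex site's index falls inside a simplex range."""
    if method == "exact":
        dist = stats.binom(depth, 2 / ploidy)
        lo_count = int(np.ceil(rng_range.lo * depth - 1e-9))
        hi_count = int(np.floor(rng_range.hi * depth + 1e-9))
        if lo_count > hi_count:
            return 0.0
        return float(dist.cdf(hi_count) - (dist.cdf(lo_count - 1) if lo_count > 0 else 0.0))
    sim = simulate_index_distribution(ploidy, 2, depth, n_reps, seed)
    return sim.fraction_within(rng_range.lo, rng_range.hi)


def minimum_depth(
    ploidy: int,
    confidence: float = 0.95,
    criterion: Literal["duplex_leakage"] = "duplex_leakage",
    depth_grid: Sequence[int] = tuple(range(10, 201, 5)),
    n_reps: int = 10_000,
    seed: int = 0,
    extraction: ExtractionRange | None = None,
    method: Literal["simulate", "exact"] = "exact",
) -> int | None:
    """Smallest depth on the grid meeting the discrimination criterion.

    Default criterion: the probability that a duplex site's index lands inside
    the simplex extraction range ("duplex leakage") is at most 1 - confidence.
    If ``extraction`` is None the range is recomputed per depth from the
    simplex distribution at the same confidence.  Returns None when no depth on
    the grid satisfies the criterion.
    """
    if criterion != "duplex_leakage":
        raise ValueError(f"unknown criterion {criterion!r}")
    grid = list(depth_grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("depth_grid must be non-empty and strictly ascending")
    for i, depth in enumerate(grid):
        rng_range = extraction
        if rng_range is None:
            rng_range = extraction_range(
                ploidy, depth, confidence, n_reps, seed + i, method
            )
        leak = duplex_leakage(ploidy, depth, rng_range, n_reps, seed + 10_000 + i, method)
        if leak <= 1 - confidence:
            return depth
    return None
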