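"""Sliding-window SNP-index / delta-SNP-index genome scan with simulated null bands.

The delta SNP index of a site is the difference between the two bulks' SNP
indices; under no linkage between genotype and bulk membership its
distribution depends only on read depth, bulk size and the segregation model,
so depth-indexed confidence bands can be simulated under that null and SNPs
falling outside them flagged.  Windows follow the method's defaults: 2 Mb
windows advanced in 50 kb steps, anchored at position 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import DosageDistribution, progeny_dosage_distribution
from .snpindex import _natural_key

__all__ = [
    "CIBand",
    "add_delta_snp_index",
    "sliding_window",
    "null_ci",
    "fisher_test",
    "add_fisher_p",
    "fraction_beyond_ci",
    "reciprocal_comparison",
]

DEFAULT_WINDOW_BP = 2_000_000
DEFAULT_STEP_BP = 50_000


def add_delta_snp_index(table: pd.DataFrame, carrier_bulk: str = "a") -> pd.DataFrame:
    """Add ``delta = index(carrier bulk) - index(other bulk)``.

    ``carrier_bulk`` names the bulk sharing the donor (P2) phenotype, so a QTL
    appears as a positive delta peak with the other bulk's index near zero.
    The orientation is recorded in ``table.attrs["carrier_bulk"]``.
    """
    if carrier_bulk not in ("a", "b"):
        raise ValueError("carrier_bulk must be 'a' or 'b'")
    out = table.copy()
    sign = 1.0 if carrier_bulk == "a" else -1.0
    out["delta"] = sign * (out["bulk_a_index"] - out["bulk_b_index"])
    out.attrs["carrier_bulk"] = carrier_bulk
    return out


def _window_starts(chrom_len: int, window_bp: int, step_bp: int) -> np.ndarray:
    return np.arange(1, chrom_len + 1, step_bp, dtype=np.int64)


def _chrom_lengths(table: pd.DataFrame, chrom_lengths: Mapping[str, int] | None) -> dict[str, int]:
    if chrom_lengths is not None:
        return dict(chrom_lengths)
    return {c: int(g["pos"].max()) for c, g in table.groupby("chrom", sort=False)}


def sliding_window(
    records: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    chrom_lengths: Mapping[str, int] | None = None,
    value_columns: Sequence[str] = ("bulk_a_index", "bulk_b_index", "delta"),
) -> pd.DataFrame:
    """Window means of the given columns over [start, start + window_bp - 1].

    Records must be position-sorted within each chromosome.  Windows are
    anchored at 1 and advanced by ``step_bp``; terminal windows truncate at the
    chromosome end.  Empty windows are emitted with ``n_snps == 0`` and NaN
    means (never zero-filled).
    """
    lengths = _chrom_lengths(records, chrom_lengths)
    frames = []
    for chrom in sorted(lengths, key=_natural_key):
        sub = records.loc[records["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"records not sorted by position on {chrom}")
        starts = _window_starts(lengths[chrom], window_bp, step_bp)
        ends = np.minimum(starts + window_bp - 1, lengths[chrom])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        # prefix sums give O(1) window means
        data: dict[str, np.ndarray] = {}
        for col in value_columns:
            if col not in sub.columns:
                continue
            csum = np.concatenate([[0.0], np.cumsum(sub[col].to_numpy(dtype=float))])
            with np.errstate(invalid="ignore"):
                data["mean_" + col] = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "window_start": starts, "window_end": ends, "n_snps": n, **data}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "window_start", "window_end", "n_snps"])
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CIBand:
    """Depth-indexed quantile envelope of the null delta-SNP-index distribution.

    ``lo``/``hi`` have shape (n_levels, n_depths); between grid depths the
    bounds are interpolated linearly, outside the grid they clamp to the
    nearest grid depth.
    """

    depth_grid: np.ndarray
    levels: tuple[float, ...]
    lo: np.ndarray
    hi: np.ndarray
    ploidy: int
    n_bulk: int
    n_reps: int
    seed: int

    def interval(self, depth: float | np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
        i = self.levels.index(level)
        return (
            np.interp(depth, self.depth_grid, self.lo[i]),
            np.interp(depth, self.depth_grid, self.hi[i]),
        )

    def outside(self, delta: np.ndarray, depth: np.ndarray, level: float) -> np.ndarray:
        lo, hi = self.interval(depth, level)
        return (delta < lo) | (delta > hi)


def null_ci(
    ploidy: int,
    n_bulk_individuals: int,
    depth_grid: Sequence[int],
    segregation: DosageDistribution | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    levels: Sequence[float] = (0.90, 0.95, 0.99),
) -> CIBand:
    """Simulate null confidence bands for the delta SNP index.

    Per replicate and depth: each bulk's ``n_bulk_individuals`` dosages are
    drawn from the segregation model (default simplex x nulliplex F1, 1:1)
    independently of phenotype; the bulk allele frequency is the dosage sum
    over ``n_bulk * ploidy`` chromosomes; read counts are binomial at the given
    depth; delta is the difference of the two bulk indices.  Bands are central
    empirical quantile intervals per level.
    """
    grid = np.asarray(sorted(set(int(d) for d in depth_grid)), dtype=int)
    if grid.size == 0:
        raise ValueError("depth_grid must be non-empty")
    if segregation is None:
        segregation = progeny_dosage_distribution(ploidy, 0, 1)
    levels = tuple(sorted(levels))
    support = np.array(segregation.support())
    probs = np.array([segregation.as_floats()[k] for k in support])
    rng = np.random.default_rng(seed)
    lo = np.empty((len(levels), grid.size))
    hi = np.empty((len(levels), grid.size))
    n_chrom = n_bulk_individuals * ploidy
    for j, depth in enumerate(grid):
        counts = rng.multinomial(n_bulk_individuals, probs, size=(n_reps, 2))
        freq = (counts @ support) / n_chrom
        alt = rng.binomial(depth, freq)
        delta = (alt[:, 0] - alt[:, 1]) / depth
        for i, lev in enumerate(levels):
            lo[i, j] = np.quantile(delta, (1 - lev) / 2, method="inverted_cdf")
            hi[i, j] = np.quantile(delta, (1 + lev) / 2, method="inverted_cdf")
    return CIBand(
        depth_grid=grid,
        levels=levels,
        lo=lo,
        hi=hi,
        ploidy=ploidy,
        n_bulk=n_bulk_individuals,
        n_reps=n_reps,
        seed=seed,
    )


def fisher_test(alt_a: int, ref_a: int, alt_b: int, ref_b: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 (alt, ref) x (bulk A, bulk B) table."""
    if min(alt_a, ref_a, alt_b, ref_b) < 0:
        raise ValueError("counts must be non-negative")
    if alt_a + ref_a == 0 or alt_b + ref_b == 0:
        raise ValueError("zero-depth row: test undefined")
    _, p = stats.fisher_exact([[alt_a, ref_a], [alt_b, ref_b]], alternative="two-sided")
    return float(p)


def add_fisher_p(table: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Fisher's exact p comparing bulk A and bulk B allele counts."""
    out = table.copy()
    ps = np.empty(len(out))
    cols = out[["bulk_a_alt_depth", "bulk_a_depth", "bulk_b_alt_depth", "bulk_b_depth"]].to_numpy()
    for i, (aa, da, ab, db) in enumerate(cols):
        ps[i] = fisher_test(int(aa), int(da - aa), int(ab), int(db - ab))
    out["fisher_p"] = ps
    return out


def snp_band_depth(table: pd.DataFrame) -> np.ndarray:
    """Depth used to look up the null band for a SNP: harmonic mean of the bulk depths.

    The band is simulated with a common depth d for both bulks, where the
    read-sampling variance of delta is proportional to 2/d; with unequal
    observed depths it is proportional to 1/d_A + 1/d_B, so the harmonic mean
    is the variance-matching one-number summary.
    """
    da = table["bulk_a_depth"].to_numpy(dtype=float)
    db = table["bulk_b_depth"].to_numpy(dtype=float)
    return 2.0 / (1.0 / np.maximum(da, 1) + 1.0 / np.maximum(db, 1))


def fraction_beyond_ci(
    records: pd.DataFrame,
    band: CIBand,
    level: float,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window fraction of SNPs whose delta lies outside the null band."""
    tagged = records.copy()
    depth = snp_band_depth(tagged)
    tagged["_beyond"] = band.outside(tagged["delta"].to_numpy(), depth, level).astype(float)
    win = sliding_window(
        tagged, window_bp, step_bp, chrom_lengths, value_columns=("_beyond",)
    )
    return win.rename(columns={"mean__beyond": "frac_beyond"})


def genome_fraction_beyond(records: pd.DataFrame, band: CIBand, level: float) -> float:
    """Genome-wide fraction of SNPs with delta outside the band (calibration check)."""
    depth = snp_band_depth(records)
    return float(band.outside(records["delta"].to_numpy(), depth, level).mean())


def reciprocal_comparison(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> tuple[float, float]:
    """Chi-square comparison of candidate-SNP proportions between reciprocal runs.

    Each argument is (candidate SNPs, total detected SNPs) for one
    parent-specific analysis.  Comparing proportions rather than raw counts is
    the "correction by total number of detected SNPs".  Returns (statistic, p)
    from the uncorrected 2x2 Pearson chi-square.
    """
    (ca, ta), (cb, tb) = counts_a, counts_b
    if not (ta >= ca >= 0 and tb >= cb >= 0):
        raise ValueError("require totals >= candidates >= 0")
    if ta == 0 or tb == 0:
        raise ValueError("zero total count")
    table = np.array([[ca, ta - ca], [cb, tb - cb]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 0.0, 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
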