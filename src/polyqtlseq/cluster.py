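"""Zero-index SNP cluster histograms and candidate-region calling.

The decisive QTL signal of the method: donor-simplex SNPs whose SNP index in
the bulk LACKING the donor phenotype is zero (or near zero) cluster tightly
around the causal locus, because those progeny carry none of the donor
haplotype there.  This module bins such SNPs into 1 Mb intervals, calls
candidate regions as bins enriched far beyond the genome-wide background, and
lists marker-candidate SNPs (index exactly 0 in the target bulk) inside a
region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .snpindex import _natural_key, sort_by_position

__all__ = [
    "CandidateRegion",
    "count_low_index_snps",
    "call_candidate_regions",
    "marker_candidates",
]

DEFAULT_BIN_BP = 1_000_000


@dataclass(frozen=True)
class CandidateRegion:
    """A run of 1 Mb bins enriched for zero-index SNPs (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    zero_count: int  # zero-index SNPs summed over the region's bins
    max_bin_count: int  # hottest single bin
    n_bins: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")


def _bulk_col(target_bulk: str) -> str:
    if target_bulk not in ("a", "b"):
        raise ValueError("target_bulk must be 'a' or 'b'")
    return f"bulk_{target_bulk}_index"


def count_low_index_snps(
    simplex_table: pd.DataFrame,
    target_bulk: str = "b",
    bin_bp: int = DEFAULT_BIN_BP,
    thresholds: Sequence[float] = (0.0, 0.01, 0.02),
    chrom_lengths: Mapping[str, int] | None = None,
    round_index: bool = False,
) -> pd.DataFrame:
    """Per-bin counts of low-index SNPs in the target bulk, in disjoint classes.

    Classes are (index == t0), (t0 < index <= t1), (t1 < index <= t2) for the
    default thresholds (0, 0.01, 0.02); stacking them reproduces the nested
    <=0.01 / <=0.02 view.  A SNP at position ``pos`` falls in bin
    ``floor((pos - 1) / bin_bp)`` so bins are 1-based closed intervals
    [1, bin_bp], [bin_bp + 1, 2 bin_bp], ...  All bins of each chromosome are
    emitted, including empty ones.  ``round_index`` applies the thresholds to
    the index rounded to 2 decimals instead of the raw value.
    """
    t0, t1, t2 = thresholds
    col = _bulk_col(target_bulk)
    idx = simplex_table[col].to_numpy(dtype=float) if len(simplex_table) else np.array([])
    if round_index:
        idx = np.round(idx, 2)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(g["pos"].max()) for c, g in simplex_table.groupby("chrom", sort=False)
        }
    frames = []
    for chrom in sorted(chrom_lengths, key=_natural_key):
        n_bins = max(1, int(np.ceil(chrom_lengths[chrom] / bin_bp)))
        sub_mask = (simplex_table["chrom"] == chrom).to_numpy() if len(simplex_table) else np.array([], bool)
        pos = simplex_table["pos"].to_numpy()[sub_mask] if len(simplex_table) else np.array([], int)
        sub_idx = idx[sub_mask] if len(simplex_table) else idx
        bins = (pos - 1) // bin_bp
        counts = {}
        for name, mask in (
            ("n_zero", sub_idx == t0),
            ("n_le_t1", (sub_idx > t0) & (sub_idx <= t1)),
            ("n_le_t2", (sub_idx > t1) & (sub_idx <= t2)),
        ):
            counts[name] = np.bincount(bins[mask], minlength=n_bins)[:n_bins]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": np.arange(n_bins, dtype=np.int64) * bin_bp + 1,
                    **counts,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "bin_start", "n_zero", "n_le_t1", "n_le_t2"])
    out = pd.concat(frames, ignore_index=True)
    out.attrs["bin_bp"] = bin_bp
    out.attrs["thresholds"] = tuple(thresholds)
    out.attrs["target_bulk"] = target_bulk
    return out


def default_min_count(histograms: pd.DataFrame) -> int:
    """Background-aware threshold: max(3, Poisson 99.9% quantile of the mean).

    The genome-wide mean zero-class count per bin sets a Poisson background;
    a bin is hot when its count reaches the 99.9% quantile of that background,
    but never below 3 supporting SNPs.
    """
    mean = float(histograms["n_zero"].mean()) if len(histograms) else 0.0
    if mean <= 0:
        return 3
    return max(3, int(stats.poisson.ppf(0.999, mean)))


def call_candidate_regions(
    histograms: pd.DataFrame,
    min_count: int | None = None,
    merge_gap_bins: int = 2,
    bin_bp: int | None = None,
) -> list[CandidateRegion]:
    """Bins with zero-class count >= min_count, merged across gaps <= merge_gap_bins.

    Returns regions sorted by descending zero-index support (ties by position),
    each a 1-based closed interval spanning its merged bins.
    """
    if bin_bp is None:
        bin_bp = int(histograms.attrs.get("bin_bp", DEFAULT_BIN_BP))
    if min_count is None:
        min_count = default_min_count(histograms)
    regions: list[CandidateRegion] = []
    for chrom, grp in histograms.groupby("chrom", sort=False):
        grp = grp.sort_values("bin_start")
        hot = grp.loc[grp["n_zero"] >= min_count]
        if hot.empty:
            continue
        bin_ids = ((hot["bin_start"].to_numpy() - 1) // bin_bp).astype(int)
        zero = hot["n_zero"].to_numpy()
        run_start = 0
        for i in range(1, len(bin_ids) + 1):
            if i == len(bin_ids) or bin_ids[i] - bin_ids[i - 1] - 1 > merge_gap_bins:
                ids = bin_ids[run_start:i]
                lo_bin, hi_bin = int(ids[0]), int(ids[-1])
                member = (grp["bin_start"] >= lo_bin * bin_bp + 1) & (
                    grp["bin_start"] <= hi_bin * bin_bp + 1
                )
                total = int(grp.loc[member, "n_zero"].sum())
                regions.append(
                    CandidateRegion(
                        chrom=str(chrom),
                        start=lo_bin * bin_bp + 1,
                        end=(hi_bin + 1) * bin_bp,
                        zero_count=total,
                        max_bin_count=int(zero[run_start:i].max()),
                        n_bins=hi_bin - lo_bin + 1,
                    )
                )
                run_start = i
    regions.sort(key=lambda r: (-r.zero_count, _natural_key(r.chrom), r.start))
    return regions


def marker_candidates(
    simplex_table: pd.DataFrame,
    region: CandidateRegion,
    target_bulk: str = "b",
    ploidy: int = 4,
) -> pd.DataFrame:
    """SNPs in the region with target-bulk index exactly 0, ranked for marker design.

    The best marker candidates sit on the donor haplotype and segregate
    cleanly: rank by closeness of the opposite (carrier) bulk's index to
    1/ploidy — in a bulk where every member carries one copy of the donor
    haplotype, a coupled simplex SNP contributes one alternate chromosome per
    ploidy homologues — then by P2 depth (descending), then (chrom, pos).
    """
    col = _bulk_col(target_bulk)
    opp = _bulk_col("a" if target_bulk == "b" else "b")
    sub = simplex_table.loc[
        (simplex_table["chrom"] == region.chrom)
        & (simplex_table["pos"] >= region.start)
        & (simplex_table["pos"] <= region.end)
        & (simplex_table[col] == 0.0)
    ].copy()
    if sub.empty:
        return sub
    sub["_dist"] = (sub[opp] - 1.0 / ploidy).abs()
    sub = sort_by_position(sub)  # deterministic tiebreak baseline
    sub = sub.sort_values(["_dist", "p2_depth"], ascending=[True, False], kind="stable")
    return sub.drop(columns="_dist").reset_index(drop=True)
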