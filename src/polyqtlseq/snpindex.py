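"""SNP-index computation, parent-consensus reference and the simplex filter cascade.

The SNP index of a site is the fraction of reads carrying the alternate base,
``alt_depth / depth``.  The pipeline extracts SNPs that are simplex in the
donor parent P2 and absent from the recurrent parent P1 in three stages:

* filter 1 — drop sites still called as variants when P1 reads are re-aligned
  to the P1 consensus reference (spurious, alignment-artifact SNPs);
* filter 2 — keep sites where BOTH phenotype bulks have depth within
  [min_depth, max_depth] and SNP index <= simplex_max (the expected upper bound
  for a mixture of nulliplex and simplex individuals);
* filter 3 — keep sites where P2 looks simplex (depth in range, index within
  [simplex_min, simplex_max]) and P1 carries (essentially) no alternate reads.

All tables are pandas DataFrames in the allele-count schema
``chrom, pos, ref, alt, depth, alt_depth`` (1-based, inclusive coordinates);
filtered tables gain a ``snp_index`` column.  All threshold comparisons are
inclusive at the stated bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COUNT_COLUMNS",
    "FilterParams",
    "FILTER_PRESETS",
    "PLOIDY_OF_PRESET",
    "compute_snp_index",
    "build_parent_reference",
    "filter1_spurious",
    "filter2_bulk_simplex",
    "filter3_p2_simplex",
    "run_filters",
]

#: canonical allele-count table columns
COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_depth"]


@dataclass(frozen=True)
class FilterParams:
    """Depth and SNP-index thresholds of the simplex filter cascade."""

    min_depth: int
    max_depth: int
    simplex_min: float
    simplex_max: float
    p1_zero_max_alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.max_depth <= self.min_depth:
            raise ValueError("require 1 <= min_depth < max_depth")
        if not (0.0 < self.simplex_min < self.simplex_max < 1.0):
            raise ValueError("require 0 < simplex_min < simplex_max < 1")
        if self.p1_zero_max_alt_reads < 0:
            raise ValueError("p1_zero_max_alt_reads must be >= 0")


_TETRAPLOID = FilterParams(min_depth=40, max_depth=500, simplex_min=0.10, simplex_max=0.36)
_HEXAPLOID = FilterParams(min_depth=50, max_depth=800, simplex_min=0.08, simplex_max=0.25)

#: Named parameter presets.  The ``_half`` / ``_quarter`` variants relax the
#: minimum depth to 25 / 15 for runs with half or a quarter of the read data.
FILTER_PRESETS: dict[str, FilterParams] = {
    "tetraploid_potato": _TETRAPLOID,
    "hexaploid_sweetpotato": _HEXAPLOID,
    "tetraploid_potato_half": replace(_TETRAPLOID, min_depth=25),
    "tetraploid_potato_quarter": replace(_TETRAPLOID, min_depth=15),
}

PLOIDY_OF_PRESET: dict[str, int] = {
    "tetraploid_potato": 4,
    "hexaploid_sweetpotato": 6,
    "tetraploid_potato_half": 4,
    "tetraploid_potato_quarter": 4,
}


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    if (df["alt_depth"] > df["depth"]).any():
        bad = df.index[df["alt_depth"] > df["depth"]][0]
        raise ValueError(f"alt_depth > depth at row {bad}")
    return df


def compute_snp_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Add ``snp_index = alt_depth / depth``; sites with depth 0 are excluded.

    Depth-0 sites have an undefined ratio and are dropped (logged), never
    treated as index 0.
    """
    _validate_counts(counts)
    n_zero = int((counts["depth"] == 0).sum())
    if n_zero:
        logger.info("excluding %d zero-depth sites", n_zero)
    out = counts.loc[counts["depth"] > 0].copy()
    out["snp_index"] = out["alt_depth"] / out["depth"]
    return out


def build_parent_reference(
    reference: Mapping[str, str], p1_calls: pd.DataFrame
) -> dict[str, str]:
    """Substitute P1 majority bases into the reference (consensus construction).

    Positions where the P1 SNP index is strictly greater than 0.5 receive the
    alternate base; all other positions (including index exactly 0.5) are left
    unchanged.  Sequence lengths are preserved.
    """
    calls = p1_calls
    if "snp_index" not in calls.columns:
        calls = compute_snp_index(calls)
    out = {name: bytearray(seq, "ascii") for name, seq in reference.items()}
    subs = calls.loc[calls["snp_index"] > 0.5]
    for chrom, pos, alt in zip(subs["chrom"], subs["pos"], subs["alt"]):
        if chrom not in out:
            raise ValueError(f"unknown chromosome {chrom!r} in P1 calls")
        if not (1 <= pos <= len(out[chrom])):
            raise ValueError(f"position {chrom}:{pos} beyond chromosome end")
        out[chrom][pos - 1] = ord(alt)
    return {name: seq.decode("ascii") for name, seq in out.items()}


def filter1_spurious(
    p1_self_alignment: pd.DataFrame, min_alt_reads: int = 1
) -> set[tuple[str, int]]:
    """Sites still variant on P1 self-alignment: spurious, excluded downstream."""
    _validate_counts(p1_self_alignment)
    bad = p1_self_alignment.loc[p1_self_alignment["alt_depth"] >= min_alt_reads]
    return set(zip(bad["chrom"], bad["pos"]))


def _passes_bulk(df: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    ok = (
        (df["depth"] >= params.min_depth)
        & (df["depth"] <= params.max_depth)
        & (df["snp_index"] <= params.simplex_max)
    )
    return df.loc[ok]


def _keys(df: pd.DataFrame) -> set[tuple[str, int, str]]:
    return set(zip(df["chrom"], df["pos"], df["alt"]))


def filter2_bulk_simplex(
    bulk_a: pd.DataFrame, bulk_b: pd.DataFrame, params: FilterParams
) -> set[tuple[str, int, str]]:
    """Sites where BOTH bulks have depth in range and index <= simplex_max.

    A site present in only one bulk fails (conservative: never imputed).
    """
    a = compute_snp_index(bulk_a) if "snp_index" not in bulk_a.columns else bulk_a
    b = compute_snp_index(bulk_b) if "snp_index" not in bulk_b.columns else bulk_b
    keys = _keys(_passes_bulk(a, params)) & _keys(_passes_bulk(b, params))
    only_one = _keys(a) ^ _keys(b)
    if only_one:
        logger.info("filter2: %d sites present in only one bulk dropped", len(only_one))
    return keys


def filter3_p2_simplex(
    p2: pd.DataFrame, p1: pd.DataFrame, params: FilterParams
) -> set[tuple[str, int, str]]:
    """Sites simplex in P2 (depth and index in range) and absent from P1.

    "Absent from P1" means at most ``p1_zero_max_alt_reads`` alternate reads
    (default 0: SNP index exactly zero on the P1 alignment).
    """
    p2i = compute_snp_index(p2) if "snp_index" not in p2.columns else p2
    ok2 = (
        (p2i["depth"] >= params.min_depth)
        & (p2i["depth"] <= params.max_depth)
        & (p2i["snp_index"] >= params.simplex_min)
        & (p2i["snp_index"] <= params.simplex_max)
    )
    p2_keys = _keys(p2i.loc[ok2])
    _validate_counts(p1)
    p1_ok = p1.loc[p1["alt_depth"] <= params.p1_zero_max_alt_reads]
    p1_keys = _keys(p1_ok)
    return p2_keys & p1_keys


def _majority_alt(df: pd.DataFrame, sample: str = "") -> pd.DataFrame:
    """Resolve multi-alternate positions: keep the majority alternate, drop exact ties."""
    _validate_counts(df)
    dup = df.duplicated(["chrom", "pos"], keep=False)
    if not dup.any():
        return df
    uni = df.loc[~dup]
    multi = df.loc[dup]
    keep_rows = []
    for (_chrom, _pos), grp in multi.groupby(["chrom", "pos"], sort=False):
        top = grp["alt_depth"].max()
        winners = grp.loc[grp["alt_depth"] == top]
        if len(winners) > 1:
            logger.info(
                "%s: tie between alternates at %s:%s, site dropped", sample, _chrom, _pos
            )
            continue
        keep_rows.append(winners)
    out = pd.concat([uni, *keep_rows], ignore_index=True) if keep_rows else uni.copy()
    return out


def _natural_key(chrom: str) -> tuple:
    import re

    return tuple(
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", str(chrom))
        if part != ""
    )


def sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by natural chromosome order (chr2 < chr10) then position."""
    order = sorted(range(len(df)), key=lambda i: (_natural_key(df["chrom"].iat[i]), df["pos"].iat[i]))
    return df.iloc[order].reset_index(drop=True)


def run_filters(
    p1_self: pd.DataFrame,
    p1: pd.DataFrame,
    p2: pd.DataFrame,
    bulk_a: pd.DataFrame,
    bulk_b: pd.DataFrame,
    params: FilterParams,
    spurious_min_alt_reads: int = 1,
) -> pd.DataFrame:
    """Full cascade: inner-join of sites surviving filters 1, 2 and 3.

    Returns the P2-specific simplex SNP table with one row per retained site
    and, for each of P1/P2/bulk A/bulk B, its depth, alternate depth and SNP
    index (columns ``p1_depth`` ... ``bulk_b_index``), sorted by (chrom, pos).
    Sites whose alternate allele conflicts across samples do not join and are
    dropped.
    """
    p1 = _majority_alt(p1, "p1")
    p2 = _majority_alt(p2, "p2")
    bulk_a = _majority_alt(bulk_a, "bulk_a")
    bulk_b = _majority_alt(bulk_b, "bulk_b")

    excluded = filter1_spurious(p1_self, spurious_min_alt_reads)
    keep2 = filter2_bulk_simplex(bulk_a, bulk_b, params)
    keep3 = filter3_p2_simplex(p2, p1, params)
    keep = {k for k in keep2 & keep3 if (k[0], k[1]) not in excluded}
    if not keep:
        cols = ["chrom", "pos", "ref", "alt"] + [
            f"{s}_{f}" for s in ("p1", "p2", "bulk_a", "bulk_b")
            for f in ("depth", "alt_depth", "index")
        ]
        return pd.DataFrame(columns=cols)

    def _narrow(df: pd.DataFrame, tag: str, with_ref: bool) -> pd.DataFrame:
        d = compute_snp_index(df) if "snp_index" not in df.columns else df
        cols = ["chrom", "pos", "ref", "alt"] if with_ref else ["chrom", "pos", "alt"]
        out = d[cols + ["depth", "alt_depth", "snp_index"]].copy()
        return out.rename(
            columns={
                "depth": f"{tag}_depth",
                "alt_depth": f"{tag}_alt_depth",
                "snp_index": f"{tag}_index",
            }
        )

    merged = _narrow(p2, "p2", with_ref=True)
    for tag, df in (("p1", p1), ("bulk_a", bulk_a), ("bulk_b", bulk_b)):
        merged = merged.merge(_narrow(df, tag, with_ref=False), on=["chrom", "pos", "alt"], how="inner")
    key = list(zip(merged["chrom"], merged["pos"], merged["alt"]))
    merged = merged.loc[[k in keep for k in key]]
    merged = merged[
        ["chrom", "pos", "ref", "alt"]
        + [f"{s}_{f}" for s in ("p1", "p2", "bulk_a", "bulk_b") for f in ("depth", "alt_depth", "index")]
    ]
    return sort_by_position(merged)
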