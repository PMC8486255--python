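"""Model/Results facade over the whole pipeline.

``PolyploidQtlSeq`` is built from the five allele-count tables (two parents,
two phenotype bulks, P1 self-alignment) plus the design parameters; ``fit``
runs the simplex filter cascade, the sliding-window delta-SNP-index scan with
simulated null confidence bands, per-SNP Fisher tests and the zero-index
cluster scan, returning a ``QtlSeqResults`` carrying every intermediate table,
the called candidate regions and ranked marker-candidate SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import scan as _scan
from . import snpindex as _snpindex
from .simulate import CrossConfig, CrossTruth, simulate_counts
from .snpindex import FILTER_PRESETS, PLOIDY_OF_PRESET, FilterParams

__all__ = ["PolyploidQtlSeq", "QtlSeqResults"]

SAMPLES = ("p1", "p2", "bulk_a", "bulk_b", "p1_self")


class PolyploidQtlSeq:
    """Polyploid bulked-segregant QTL scan from per-site allele counts.

    Parameters
    ----------
    counts
        Mapping with keys ``p1, p2, bulk_a, bulk_b, p1_self``, each an
        allele-count DataFrame (``chrom, pos, ref, alt, depth, alt_depth``).
    ploidy
        Even ploidy of the cross (4 tetraploid, 6 hexaploid).
    filter_params
        Thresholds of the simplex filter cascade; defaults to the tetraploid
        preset (depth 40-500, index 0.10-0.36) or the hexaploid preset when
        ``ploidy == 6``.
    bulk_size
        Individuals per bulk (needed by the null-band simulation).
    carrier_bulk
        Which bulk ("a" or "b") shares the donor-parent phenotype; fixes the
        sign convention delta = index(carrier) - index(other) and which bulk
        the zero-index cluster scan targets (the other one).
    """

    def __init__(
        self,
        counts: Mapping[str, pd.DataFrame],
        ploidy: int = 4,
        filter_params: FilterParams | None = None,
        bulk_size: int = 23,
        window_bp: int = _scan.DEFAULT_WINDOW_BP,
        step_bp: int = _scan.DEFAULT_STEP_BP,
        levels: Sequence[float] = (0.95, 0.99),
        carrier_bulk: str = "a",
        chrom_lengths: Mapping[str, int] | None = None,
        truth: CrossTruth | None = None,
    ) -> None:
        missing = [s for s in SAMPLES if s not in counts]
        if missing:
            raise ValueError(f"missing count tables: {missing}")
        self.counts = dict(counts)
        self.ploidy = ploidy
        if filter_params is None:
            filter_params = FILTER_PRESETS["hexaploid_sweetpotato" if ploidy == 6 else "tetraploid_potato"]
        self.filter_params = filter_params
        self.bulk_size = bulk_size
        self.window_bp = window_bp
        self.step_bp = step_bp
        self.levels = tuple(sorted(levels))
        self.carrier_bulk = carrier_bulk
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self.truth = truth

    @classmethod
    def from_preset(cls, counts: Mapping[str, pd.DataFrame], preset: str, **kwargs) -> "PolyploidQtlSeq":
        """Build from a named threshold preset (``tetraploid_potato`` etc.)."""
        return cls(
            counts,
            ploidy=PLOIDY_OF_PRESET[preset],
            filter_params=FILTER_PRESETS[preset],
            **kwargs,
        )

    @classmethod
    def from_tsv(
        cls,
        p1: str | Path,
        p2: str | Path,
        bulk_a: str | Path,
        bulk_b: str | Path,
        p1_self: str | Path,
        **kwargs,
    ) -> "PolyploidQtlSeq":
        from .io import read_counts_tsv

        counts = {
            "p1": read_counts_tsv(p1),
            "p2": read_counts_tsv(p2),
            "bulk_a": read_counts_tsv(bulk_a),
            "bulk_b": read_counts_tsv(bulk_b),
            "p1_self": read_counts_tsv(p1_self),
        }
        return cls(counts, **kwargs)

    @classmethod
    def from_simulation(cls, config: CrossConfig, rule: str = "phenotype", **kwargs) -> "PolyploidQtlSeq":
        """Simulate a cross and build the model from its count tables."""
        tables, truth = simulate_counts(config, rule=rule)
        lengths = {c: config.chrom_length_bp for c in config.chrom_names}
        kwargs.setdefault("ploidy", config.ploidy)
        kwargs.setdefault("bulk_size", config.bulk_size)
        kwargs.setdefault("chrom_lengths", lengths)
        return cls(tables, truth=truth, **kwargs)

    def fit(
        self,
        seed: int = 0,
        n_reps: int = 10_000,
        depth_grid: Sequence[int] | None = None,
        fisher: bool = True,
    ) -> "QtlSeqResults":
        """Run filters, scan and cluster analysis; returns the results object."""
        snps = _snpindex.run_filters(
            self.counts["p1_self"],
            self.counts["p1"],
            self.counts["p2"],
            self.counts["bulk_a"],
            self.counts["bulk_b"],
            self.filter_params,
        )
        snps = _scan.add_delta_snp_index(snps, carrier_bulk=self.carrier_bulk)
        if fisher and len(snps):
            snps = _scan.add_fisher_p(snps)

        if depth_grid is None:
            if len(snps):
                d = _scan.snp_band_depth(snps)
                lo = max(self.filter_params.min_depth // 2, 5)
                hi = int(np.ceil(d.max())) + 10
            else:
                lo, hi = self.filter_params.min_depth, self.filter_params.min_depth * 3
            depth_grid = np.unique(np.linspace(lo, hi, 12, dtype=int))
        band = _scan.null_ci(
            self.ploidy,
            self.bulk_size,
            depth_grid=depth_grid,
            n_reps=n_reps,
            seed=seed,
            levels=self.levels,
        )

        windows = _scan.sliding_window(
            snps, self.window_bp, self.step_bp, self.chrom_lengths
        )
        exceedance = {}
        for level in self.levels:
            frac = _scan.fraction_beyond_ci(
                snps, band, level, self.window_bp, self.step_bp, self.chrom_lengths
            )
            windows[f"frac_beyond_{level:g}"] = frac["frac_beyond"].to_numpy()
            exceedance[level] = (
                _scan.genome_fraction_beyond(snps, band, level) if len(snps) else float("nan")
            )

        target_bulk = "b" if self.carrier_bulk == "a" else "a"
        histograms = _cluster.count_low_index_snps(
            snps, target_bulk=target_bulk, chrom_lengths=self.chrom_lengths
        )
        regions = _cluster.call_candidate_regions(histograms)
        markers = (
            _cluster.marker_candidates(snps, regions[0], target_bulk, self.ploidy)
            if regions
            else snps.iloc[0:0]
        )
        return QtlSeqResults(
            model=self,
            simplex_snps=snps,
            windows=windows,
            band=band,
            genome_exceedance=exceedance,
            histograms=histograms,
            candidate_regions=regions,
            marker_snps=markers,
            target_bulk=target_bulk,
        )


@dataclass
class QtlSeqResults:
    """Fitted pipeline outputs.

    Attributes
    ----------
    simplex_snps
        Donor-specific simplex SNP table surviving the filter cascade, with
        delta SNP index and Fisher p per SNP.
    windows
        Sliding-window means of both bulk indices and delta, plus per-window
        fractions of SNPs beyond each confidence band.
    band
        Depth-indexed null confidence band (:class:`polyqtlseq.scan.CIBand`).
    histograms, candidate_regions, marker_snps
        Zero-index 1 Mb histograms, called regions (best first) and ranked
        marker-candidate SNPs inside the top region.
    """

    model: PolyploidQtlSeq
    simplex_snps: pd.DataFrame
    windows: pd.DataFrame
    band: _scan.CIBand
    genome_exceedance: dict[float, float]
    histograms: pd.DataFrame
    candidate_regions: list[_cluster.CandidateRegion]
    marker_snps: pd.DataFrame
    target_bulk: str = "b"

    def summary(self) -> str:
        lines = [
            "Polyploid QTL-seq results",
            "=" * 60,
            f"ploidy: {self.model.ploidy}   bulk size: {self.model.bulk_size}"
            f"   carrier bulk: {self.model.carrier_bulk}",
            f"filters: depth {self.model.filter_params.min_depth}-"
            f"{self.model.filter_params.max_depth}, simplex index "
            f"{self.model.filter_params.simplex_min}-{self.model.filter_params.simplex_max}",
            f"donor-specific simplex SNPs retained: {len(self.simplex_snps)}",
            "genome-wide fraction of SNPs beyond null band: "
            + ", ".join(f"{lvl:.0%}: {frac:.4f}" for lvl, frac in self.genome_exceedance.items()),
            f"candidate regions (zero-index clusters in bulk {self.target_bulk.upper()}): "
            f"{len(self.candidate_regions)}",
        ]
        for r in self.candidate_regions[:5]:
            lines.append(
                f"  {r.chrom}:{r.start}-{r.end}  zero-index SNPs={r.zero_count} "
                f"(hottest bin {r.max_bin_count})"
            )
        if len(self.marker_snps):
            top = self.marker_snps.iloc[0]
            lines.append(
                f"top marker candidate: {top['chrom']}:{top['pos']} {top['ref']}>{top['alt']}"
            )
        return "\n".join(lines)

    def plot_scan(self, path: str | Path, level: float | None = None) -> None:
        """Per-chromosome bulk index, delta and band-exceedance panels."""
        from .plotting import plot_scan

        plot_scan(self, path, level=level)

    def plot_clusters(self, path: str | Path) -> None:
        from .plotting import plot_clusters

        plot_clusters(self, path)
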