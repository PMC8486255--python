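"""Whole-pipeline validation experiments on synthetic crosses.

These functions run the pipeline under its reference study conditions — the
tetraploid design with 12 x 5 Mb chromosomes, 2000 donor-simplex SNPs, bulks
of 23 at ~50x depth — and measure the properties a practitioner would check
before trusting a run: null-scan calibration, causal-locus recovery, and the
reciprocal-parent contrast.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cluster import call_candidate_regions, count_low_index_snps
from .scan import add_delta_snp_index, genome_fraction_beyond, null_ci
from .simulate import CrossConfig, sample_reads, select_bulks, simulate_cross
from .snpindex import FILTER_PRESETS, run_filters

__all__ = ["null_scan_calibration", "recovery_experiment", "duplex_exclusion_rate"]


def _null_cross_delta_table(seed: int, n_snps: int) -> pd.DataFrame:
    """Per-SNP bulk indices at donor-simplex sites of a null cross (no QTL)."""
    config = CrossConfig(
        causal=None,
        n_p2_simplex=n_snps,
        n_p1_simplex=0,
        n_duplex=0,
        n_spurious=0,
        seed=seed,
    )
    truth = simulate_cross(config)
    select_bulks(truth, rule="random")
    tables = sample_reads(truth)
    ba, bb = tables["bulk_a"], tables["bulk_b"]
    keep = ((ba["depth"] > 0) & (bb["depth"] > 0)).to_numpy()
    df = pd.DataFrame(
        {
            "chrom": ba["chrom"],
            "pos": ba["pos"],
            "bulk_a_depth": ba["depth"],
            "bulk_a_index": ba["alt_depth"] / ba["depth"].clip(lower=1),
            "bulk_b_depth": bb["depth"],
            "bulk_b_index": bb["alt_depth"] / bb["depth"].clip(lower=1),
        }
    ).loc[keep]
    return add_delta_snp_index(df)


def null_scan_calibration(
    seed: int = 0,
    n_snps: int = 10_000,
    n_crosses: int = 6,
    level: float = 0.95,
    band_reps: int = 100_000,
) -> float:
    """Fraction of null-cross SNPs falling beyond the simulated confidence band.

    Simulates ``n_crosses`` independent null crosses (no causal locus, bulks
    random) of ``n_snps`` donor-simplex SNPs each and returns the mean
    genome-wide fraction of SNPs whose delta SNP index lies outside the
    ``level`` band.  Under a correctly calibrated band this approaches
    ``1 - level``; several crosses are averaged because linked SNPs share
    bulk-composition noise, which makes the single-cross estimate noisy.
    """
    band = null_ci(
        4, 23, depth_grid=range(20, 101, 5), n_reps=band_reps, seed=seed + 500_000,
        levels=(level,),
    )
    fracs = [
        genome_fraction_beyond(_null_cross_delta_table(seed + i, n_snps), band, level)
        for i in range(n_crosses)
    ]
    return float(np.mean(fracs))


def recovery_experiment(
    n_seeds: int = 20, base_seed: int = 0, preset: str = "tetraploid_potato"
) -> dict:
    """Planted-QTL recovery and reciprocal-parent contrast over seeded replicates.

    For each replicate of the default tetraploid design: run the filter
    cascade and cluster scan, check whether the top candidate region contains
    the causal locus, then rerun the cascade with the parents' roles swapped
    (recurrent-parent-specific simplex SNPs) and count zero-index SNPs in the
    non-carrier bulk for both orientations.  Returns per-replicate results and
    the pooled chi-square comparison of zero-index proportions.
    """
    from .scan import reciprocal_comparison

    params = FILTER_PRESETS[preset]
    hits = 0
    zero_fwd = tot_fwd = zero_rev = tot_rev = 0
    per_seed = []
    for i in range(n_seeds):
        config = CrossConfig(seed=base_seed + i)
        truth = simulate_cross(config)
        select_bulks(truth)
        tables = sample_reads(truth)
        snps = run_filters(
            tables["p1_self"], tables["p1"], tables["p2"],
            tables["bulk_a"], tables["bulk_b"], params,
        )
        lengths = {c: config.chrom_length_bp for c in config.chrom_names}
        hist = count_low_index_snps(snps, "b", chrom_lengths=lengths)
        regions = call_candidate_regions(hist)
        top = regions[0] if regions else None
        hit = (
            top is not None
            and top.chrom == config.causal[0]
            and top.start <= config.causal[1] <= top.end
        )
        hits += hit
        reciprocal = run_filters(
            tables["p1_self"], tables["p2"], tables["p1"],
            tables["bulk_a"], tables["bulk_b"], params,
        )
        z_f = int((snps["bulk_b_index"] == 0).sum())
        z_r = int((reciprocal["bulk_b_index"] == 0).sum())
        zero_fwd += z_f
        tot_fwd += len(snps)
        zero_rev += z_r
        tot_rev += len(reciprocal)
        per_seed.append(
            {"seed": base_seed + i, "hit": bool(hit), "n_snps": len(snps),
             "zero_index": z_f, "n_snps_reciprocal": len(reciprocal),
             "zero_index_reciprocal": z_r}
        )
    stat, p = reciprocal_comparison((zero_fwd, tot_fwd), (zero_rev, tot_rev))
    return {
        "n_seeds": n_seeds,
        "hits": hits,
        "per_seed": per_seed,
        "pooled": {
            "zero_index": zero_fwd,
            "total": tot_fwd,
            "zero_index_reciprocal": zero_rev,
            "total_reciprocal": tot_rev,
            "chi2": stat,
            "p": p,
        },
    }


def duplex_exclusion_rate(seed: int = 0, depth: int = 40, n_reps: int = 100_000) -> float:
    """Percent of simulated tetraploid duplex sites excluded by the 0.10-0.36 window."""
    from .depth_sim import PRESET_EXTRACTION_RANGES, simulate_index_distribution

    res = simulate_index_distribution(4, 2, depth, n_reps, seed)
    rng = PRESET_EXTRACTION_RANGES[4]
    return 100.0 * (1.0 - res.fraction_within(rng.lo, rng.hi))
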