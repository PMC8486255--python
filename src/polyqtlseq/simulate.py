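"""Synthetic autopolyploid cross generator with planted causal locus.

Emulates the statistical structure of a whole-genome bulked-segregant
experiment on an F1 mapping population of an outcrossing autopolyploid:

* parents carry four SNP classes — donor-parent (P2) simplex, recurrent-parent
  (P1) simplex, P2 duplex, and spurious alignment artifacts;
* progeny are produced by random bivalent pairing of the parental homologues
  with Poisson (Haldane, no interference) crossovers, which reproduces the
  hypergeometric gamete-dosage distribution exactly;
* an optional monogenic causal locus (phenotype = carries >= 1 donor copy,
  segregating 1:1) defines the two phenotype bulks;
* reads are sampled per site as Binomial(depth, freq) with Poisson depth
  around the target coverage and a symmetric substitution-error rate.

The generated tables are pipeline-ready allele-count DataFrames for P1, P2,
both bulks and the P1 self-alignment, plus the full ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .snpindex import COUNT_COLUMNS, sort_by_position

__all__ = [
    "CrossConfig",
    "CrossTruth",
    "simulate_cross",
    "select_bulks",
    "sample_reads",
    "simulate_counts",
    "reference_genome",
]

_BASES = np.array(list("ACGT"))

SNP_CLASSES = ("p2_simplex", "p1_simplex", "duplex", "spurious")


@dataclass(frozen=True)
class CrossConfig:
    """Study design of the synthetic cross.

    Defaults mirror the tetraploid validation design: a 12 x 5 Mb genome with
    2000 donor-simplex SNPs, a monogenic causal locus at the centre of
    chromosome 5, 82 F1 progeny from which 23 carriers and 23 non-carriers are
    bulked by phenotype, ~50x coverage and a 0.1% substitution error rate.
    Recombination defaults to 1 cM/Mb.  (A population comfortably larger than
    twice the bulk size is required so that a 1:1 segregating phenotype almost
    surely yields enough individuals in each class.)
    """

    ploidy: int = 4
    n_chromosomes: int = 12
    chrom_length_bp: int = 5_000_000
    n_p2_simplex: int = 2000
    n_p1_simplex: int = 2000
    n_duplex: int = 500
    n_spurious: int = 200
    causal: tuple[str, int] | None = ("chr05", 2_500_000)
    n_progeny: int = 82
    bulk_size: int = 23
    depth_mean: float = 50.0
    fixed_depth: bool = False
    read_error_rate: float = 0.001
    recombination_cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy % 2 or self.ploidy < 2:
            raise ValueError("ploidy must be an even integer >= 2")
        if self.bulk_size * 2 > self.n_progeny:
            raise ValueError("bulk_size must be <= n_progeny / 2")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.read_error_rate < 0 or self.recombination_cm_per_mb < 0:
            raise ValueError("rates must be >= 0")
        if self.causal is not None:
            chrom, pos = self.causal
            if chrom not in self.chrom_names or not (1 <= pos <= self.chrom_length_bp):
                raise ValueError(f"causal locus {chrom}:{pos} outside the genome")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]


@dataclass
class CrossTruth:
    """Ground truth of one simulated cross.

    ``snps`` rows align with the columns of ``progeny_dosage`` and with the
    ``p1_dosage`` / ``p2_dosage`` vectors.  ``phenotype`` is None for a null
    cross (no causal locus).
    """

    config: CrossConfig
    snps: pd.DataFrame  # chrom,pos,ref,alt,snp_class,is_causal
    p1_dosage: np.ndarray
    p2_dosage: np.ndarray
    progeny_dosage: np.ndarray  # (n_progeny, n_snps)
    phenotype: np.ndarray | None
    causal_index: int | None
    bulk_a: np.ndarray | None = field(default=None)
    bulk_b: np.ndarray | None = field(default=None)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


def _unique_positions(rng: np.random.Generator, config: CrossConfig, n: int) -> pd.DataFrame:
    """n distinct (chrom, pos) pairs, uniform over the genome."""
    names = config.chrom_names
    seen: set[tuple[int, int]] = set()
    if config.causal is not None:
        seen.add((names.index(config.causal[0]), config.causal[1]))
    rows: list[tuple[int, int]] = []
    while len(rows) < n:
        c = int(rng.integers(config.n_chromosomes))
        p = int(rng.integers(1, config.chrom_length_bp + 1))
        if (c, p) in seen:
            continue
        seen.add((c, p))
        rows.append((c, p))
    return pd.DataFrame({"chrom": [names[c] for c, _ in rows], "pos": [p for _, p in rows]})


def _gamete(
    hap: np.ndarray,
    pos_bp: np.ndarray,
    chrom_len: int,
    morgans_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: random bivalent pairing, one recombinant product per bivalent."""
    ploidy = hap.shape[0]
    perm = rng.permutation(ploidy)
    out = np.empty((ploidy // 2, hap.shape[1]), dtype=np.int8)
    total_morgans = chrom_len * morgans_per_bp
    for i in range(ploidy // 2):
        a, b = perm[2 * i], perm[2 * i + 1]
        start_a = rng.random() < 0.5
        n_x = rng.poisson(total_morgans) if total_morgans > 0 else 0
        if n_x == 0:
            out[i] = hap[a] if start_a else hap[b]
            continue
        xp = np.sort(rng.uniform(0, chrom_len, n_x))
        seg = np.searchsorted(xp, pos_bp)
        use_a = (seg % 2 == 0) if start_a else (seg % 2 == 1)
        out[i] = np.where(use_a, hap[a], hap[b])
    return out


def simulate_cross(config: CrossConfig) -> CrossTruth:
    """Simulate parents and progeny; returns the full ground truth."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_p2_simplex + config.n_p1_simplex + config.n_duplex + config.n_spurious
    snps = _unique_positions(rng, config, n_total)
    classes = np.repeat(
        SNP_CLASSES,
        [config.n_p2_simplex, config.n_p1_simplex, config.n_duplex, config.n_spurious],
    )
    snps["snp_class"] = classes
    snps["is_causal"] = False
    if config.causal is not None:
        causal_row = pd.DataFrame(
            {
                "chrom": [config.causal[0]],
                "pos": [config.causal[1]],
                "snp_class": ["p2_simplex"],
                "is_causal": [True],
            }
        )
        snps = pd.concat([snps, causal_row], ignore_index=True)
    snps = sort_by_position(snps)

    ref_i = rng.integers(0, 4, size=len(snps))
    alt_i = (ref_i + rng.integers(1, 4, size=len(snps))) % 4
    snps["ref"] = _BASES[ref_i]
    snps["alt"] = _BASES[alt_i]
    snps = snps[["chrom", "pos", "ref", "alt", "snp_class", "is_causal"]]

    ploidy = config.ploidy
    n_snps = len(snps)
    p1_hap: dict[str, np.ndarray] = {}
    p2_hap: dict[str, np.ndarray] = {}
    col_of: dict[str, np.ndarray] = {}  # global column indices per chromosome
    carrier_copy = np.full(n_snps, -1, dtype=int)  # homologue carrying a simplex allele
    for chrom in config.chrom_names:
        mask = (snps["chrom"] == chrom).to_numpy()
        cols = np.flatnonzero(mask)
        col_of[chrom] = cols
        m = len(cols)
        p1_hap[chrom] = np.zeros((ploidy, m), dtype=np.int8)
        p2_hap[chrom] = np.zeros((ploidy, m), dtype=np.int8)
        cls = snps["snp_class"].to_numpy()[mask]
        for j in range(m):
            if cls[j] == "p2_simplex":
                c = int(rng.integers(ploidy))
                p2_hap[chrom][c, j] = 1
                carrier_copy[cols[j]] = c
            elif cls[j] == "p1_simplex":
                c = int(rng.integers(ploidy))
                p1_hap[chrom][c, j] = 1
                carrier_copy[cols[j]] = c
            elif cls[j] == "duplex":
                copies = rng.choice(ploidy, size=2, replace=False)
                p2_hap[chrom][copies, j] = 1
            # spurious sites carry no true allele on either parent
    snps = snps.assign(carrier_copy=carrier_copy)

    morgans_per_bp = config.recombination_cm_per_mb / 100.0 / 1e6
    progeny = np.zeros((config.n_progeny, n_snps), dtype=np.int8)
    pos_by_chrom = {c: snps["pos"].to_numpy()[col_of[c]] for c in config.chrom_names}
    for i in range(config.n_progeny):
        for chrom in config.chrom_names:
            if col_of[chrom].size == 0:
                continue
            pos_bp = pos_by_chrom[chrom]
            g1 = _gamete(p1_hap[chrom], pos_bp, config.chrom_length_bp, morgans_per_bp, rng)
            g2 = _gamete(p2_hap[chrom], pos_bp, config.chrom_length_bp, morgans_per_bp, rng)
            progeny[i, col_of[chrom]] = g1.sum(axis=0) + g2.sum(axis=0)

    p1_dosage = np.concatenate([p1_hap[c].sum(axis=0) for c in config.chrom_names]) if n_snps else np.array([], int)
    p2_dosage = np.concatenate([p2_hap[c].sum(axis=0) for c in config.chrom_names]) if n_snps else np.array([], int)
    # haplotype arrays are chromosome-blocked; realign to the sorted snp order
    order = np.concatenate([col_of[c] for c in config.chrom_names]) if n_snps else np.array([], int)
    realign = np.empty(n_snps, dtype=int)
    realign[order] = np.arange(n_snps)
    p1_dosage = p1_dosage[realign]
    p2_dosage = p2_dosage[realign]

    causal_index = None
    phenotype = None
    if config.causal is not None:
        causal_index = int(np.flatnonzero(snps["is_causal"].to_numpy())[0])
        phenotype = progeny[:, causal_index] >= 1

    return CrossTruth(
        config=config,
        snps=snps.reset_index(drop=True),
        p1_dosage=p1_dosage,
        p2_dosage=p2_dosage,
        progeny_dosage=progeny,
        phenotype=phenotype,
        causal_index=causal_index,
    )


def select_bulks(
    truth: CrossTruth,
    bulk_size: int | None = None,
    rule: Literal["phenotype", "random"] = "phenotype",
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the two bulks; bulk A = phenotype carriers, bulk B = non-carriers.

    ``rule="random"`` partitions progeny irrespective of phenotype (the null
    design).  Membership is stored on the truth object and returned.
    """
    config = truth.config
    if bulk_size is None:
        bulk_size = config.bulk_size
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    if rule == "random" or truth.phenotype is None:
        perm = rng.permutation(config.n_progeny)
        a, b = perm[:bulk_size], perm[bulk_size : 2 * bulk_size]
    elif rule == "phenotype":
        carriers = np.flatnonzero(truth.phenotype)
        non = np.flatnonzero(~truth.phenotype)
        if len(carriers) < bulk_size or len(non) < bulk_size:
            raise ValueError(
                f"insufficient progeny per phenotype class: {len(carriers)} carriers, "
                f"{len(non)} non-carriers, need {bulk_size} each"
            )
        a = rng.choice(carriers, size=bulk_size, replace=False)
        b = rng.choice(non, size=bulk_size, replace=False)
    else:
        raise ValueError(f"unknown bulk rule {rule!r}")
    truth.bulk_a, truth.bulk_b = np.sort(a), np.sort(b)
    return truth.bulk_a, truth.bulk_b


def _counts_table(
    snps: pd.DataFrame,
    freq: np.ndarray,
    depth_mean: float,
    fixed_depth: bool,
    error: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    depth = (
        np.full(len(snps), int(round(depth_mean)))
        if fixed_depth
        else rng.poisson(depth_mean, size=len(snps))
    )
    p = freq * (1 - error) + (1 - freq) * error / 3
    alt = rng.binomial(depth, p)
    out = snps[["chrom", "pos", "ref", "alt"]].copy()
    out["depth"] = depth.astype(np.int64)
    out["alt_depth"] = alt.astype(np.int64)
    return out[COUNT_COLUMNS]


def sample_reads(
    truth: CrossTruth, config: CrossConfig | None = None, seed: int | None = None
) -> dict[str, pd.DataFrame]:
    """Sample the five allele-count tables (p1, p2, bulk_a, bulk_b, p1_self).

    Bulk allele frequency at a site is the dosage sum of the bulk members over
    ``bulk_size * ploidy`` chromosomes; the parents read from their own
    dosages.  The P1 self-alignment is variant-free except at spurious sites,
    which show an alignment-artifact frequency of 0.5 in every sample.
    """
    config = config or truth.config
    if truth.bulk_a is None or truth.bulk_b is None:
        raise ValueError("bulks not selected; call select_bulks first")
    rng = np.random.default_rng(config.seed + 13 if seed is None else seed)
    ploidy = config.ploidy
    spurious = (truth.snps["snp_class"] == "spurious").to_numpy()

    def bulk_freq(members: np.ndarray) -> np.ndarray:
        f = truth.progeny_dosage[members].sum(axis=0) / (len(members) * ploidy)
        return np.where(spurious, 0.5, f)

    freqs = {
        "p1": np.where(spurious, 0.5, truth.p1_dosage / ploidy),
        "p2": np.where(spurious, 0.5, truth.p2_dosage / ploidy),
        "bulk_a": bulk_freq(truth.bulk_a),
        "bulk_b": bulk_freq(truth.bulk_b),
        "p1_self": np.where(spurious, 0.5, 0.0),
    }
    return {
        name: _counts_table(
            truth.snps, f, config.depth_mean, config.fixed_depth, config.read_error_rate, rng
        )
        for name, f in freqs.items()
    }


def simulate_counts(
    config: CrossConfig, rule: Literal["phenotype", "random"] = "phenotype"
) -> tuple[dict[str, pd.DataFrame], CrossTruth]:
    """Convenience: cross -> bulks -> reads, returning (tables, truth)."""
    truth = simulate_cross(config)
    select_bulks(truth, rule=rule)
    return sample_reads(truth), truth


def reference_genome(truth: CrossTruth, seed: int | None = None) -> dict[str, str]:
    """Random reference sequences consistent with the truth table's ref bases."""
    config = truth.config
    rng = np.random.default_rng(config.seed + 29 if seed is None else seed)
    out: dict[str, str] = {}
    for chrom in config.chrom_names:
        seq = rng.integers(0, 4, size=config.chrom_length_bp)
        sub = truth.snps.loc[truth.snps["chrom"] == chrom]
        base_codes = {b: i for i, b in enumerate(_BASES)}
        seq[sub["pos"].to_numpy() - 1] = [base_codes[b] for b in sub["ref"]]
        out[chrom] = "".join(_BASES[seq])
    return out
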