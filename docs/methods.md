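# Methods

## Dosage genetics

An autopolyploid of ploidy 2n carries an allele in dosage d ∈ {0, …, 2n}.
Assuming random bivalent pairing, no double reduction and no preferential
pairing, a gamete receives n of the 2n homologues without replacement, so
gamete dosage is hypergeometric:

    P(k | d) = C(d, k) C(2n − d, n − k) / C(2n, n).

Progeny dosage is the convolution of the two parental gamete distributions.
All of this is computed in exact `fractions.Fraction` arithmetic
(`polyqtlseq.genetics`); floats appear only at the API boundary. Whole-genome
combination counts use exact integers — (C(2n, n)²)^c for a c-chromosome F1
outcross, 3^c for a diploid F2.

The expected SNP index of dosage class d is d/2n: 0.25/0.50/0.75 for
tetraploid simplex/duplex/triplex, 1/6 … 5/6 for hexaploid classes.

## Read-depth design (`depth_sim`)

At depth D the observed index of a dosage-d site is Binomial(D, d/2n)/D.
`simulate_index_distribution` draws these directly; `extraction_range` returns
the central confidence interval of the simplex distribution (empirical
inverse-CDF quantiles, the lowest value whose CDF reaches p — chosen because
it is deterministic and matches the exact binomial oracle), widened if needed
to contain 1/2n; `minimum_depth` walks a depth grid until the *duplex leakage*
— the probability that a duplex site's index lands inside the simplex window —
drops to 1 − confidence, and returns `None` when no grid depth qualifies.

The shipped extraction windows (tetraploid 0.10–0.36 at depth ≥ 40;
hexaploid 0.08–0.25 at depth ≥ 75) are fixed presets of the method. No single
obvious quantile rule reproduces them (symmetric 95% simplex quantiles at
depth 40 give ≈0.125–0.375), so the package does not claim to re-derive them;
`extraction_range` documents its own explicit criterion instead. At depth 40
the exact tetraploid duplex leakage through 0.10–0.36 is
P(4 ≤ Bin(40, ½) ≤ 14) ≈ 4.0%, i.e. ≈96% of duplex sites are excluded.

## Filter cascade (`snpindex`)

Coordinates are 1-based and inclusive throughout; every threshold comparison
is inclusive at its stated bound, and the dash range "0.10–0.36" is read as
the closed interval. Defaults per preset:

| preset | min depth | max depth | simplex window |
|---|---|---|---|
| tetraploid_potato | 40 | 500 | 0.10–0.36 |
| hexaploid_sweetpotato | 50 | 800 | 0.08–0.25 |
| tetraploid_potato_half / _quarter | 25 / 15 | 500 | 0.10–0.36 |

The `_half`/`_quarter` presets are for runs with half or a quarter of the read
data. "P1 index of 0" in filter 3 means at most `p1_zero_max_alt_reads`
(default 0) alternate reads; a tolerance can be configured for noisy data.
Filter 3 applies the depth window to the P2 sample only — the filter as
defined names only P2 alignment criteria; the bulks get the window in
filter 2. A site missing from any required sample fails (never imputed).
Multi-alternate sites keep the majority alternate; exact ties drop the site
(logged). Consensus construction substitutes the alternate base only where
the P1 index is *strictly* greater than 0.5.

Note one deliberate asymmetry inherited from the method: filter 2 requires
index ≤ simplex_max in *both* bulks even though at a true QTL the carrier
bulk's expectation is 1/2n and the other's ≈ 0 — both sides of which satisfy
the ceiling, so the QTL signal survives.

## Genome scan (`scan`)

Δ(SNP index) = index(carrier bulk) − index(other bulk); the carrier bulk is
the one sharing the donor-parent phenotype, so a QTL appears as a positive Δ
peak. The orientation is recorded in the output metadata since the sign is a
pure convention.

Windows are anchored at position 1 and advanced by the step (defaults 2 Mb /
50 kb); terminal windows truncate at the chromosome end; empty windows are
emitted with `n_snps = 0` and NaN means, never zero-filled. Window means use
prefix sums and are verified against a brute-force rescan in the tests.

**Null confidence bands.** Under no linkage, each bulk's allele frequency at
a simplex SNP is the mean of `bulk_size` dosages drawn from the segregation
model (default simplex × nulliplex, 1:1) over `bulk_size × ploidy`
chromosomes, and reads are Binomial(depth, frequency). Bands are central
empirical quantile intervals of simulated Δ per depth on a grid, interpolated
linearly between grid depths and clamped outside the grid. The original
pipeline configuration was run in an F2 mode; the simplex-F1 segregation
model matches the actual genetics of an outcrossed polyploid cross and is the
default here, with any `DosageDistribution` accepted instead. Bands are
looked up per SNP at the *harmonic* mean of the two bulk depths (the
variance-matching summary, since Var(Δ) ∝ 1/d_A + 1/d_B while the band is
simulated at a common depth); exceedance is reported per window as the
fraction of member SNPs outside the band, following the per-SNP reading of
the band display.

Calibration: on null synthetic crosses the genome-wide fraction of SNPs
beyond the 95% band measures ≈0.055 rather than exactly 0.05. The residual
comes from depth heterogeneity — with unequal bulk depths the Δ lattice is
finer than at the band's common depth, so probability mass that the band
simulation places exactly *on* the quantile boundary falls just beyond it in
real tables. The test suite checks calibration to 0.05 ± 0.01, averaging
several null crosses because linked SNPs share bulk-composition noise and a
single cross gives a noisy estimate (per-cross SD ≈ 0.006).

Per-SNP bulk contrasts use Fisher's exact test (two-sided) on the
(alt, ref) × (bulk A, bulk B) table via `scipy.stats.fisher_exact`, verified
against direct hypergeometric enumeration. The reciprocal-parent comparison
— candidate-SNP counts from the two parent-specific analyses, each corrected
by its total detected SNPs — is an uncorrected 2×2 Pearson chi-square on
candidate vs non-candidate counts (`scipy.stats.chi2_contingency`,
`correction=False`, matching the textbook statistic).

## Cluster scan (`cluster`)

Low-index SNPs in the target (non-carrier) bulk are counted in 1 Mb bins —
bin of position p is floor((p−1)/10⁶), so bins are closed intervals
[1, 10⁶], [10⁶+1, 2·10⁶], …. The three display classes (0 / 0.01 / 0.02) are
stored disjointly (exactly 0; (0, 0.01]; (0.01, 0.02]) so that stacking
reproduces the nested ≤-threshold view while counts stay conserved.
Thresholds apply to the raw index by default; a variant applies them to the
index rounded to two decimals (`round_index=True`).

Candidate-region calling is algorithmized (the original judgement was visual):
a bin is *hot* when its zero-class count reaches
max(3, Poisson 99.9% quantile of the genome-wide mean count per bin), and hot
bins separated by ≤ 2 cold bins merge into one region. Both knobs are
overridable. On 20 null replicates of the reference design this calls 0.05
regions per genome on average.

Marker candidates are region SNPs with target-bulk index exactly 0, ranked by
closeness of the carrier bulk's index to 1/2n (a fully coupled simplex marker
in an all-carrier bulk contributes one alternate chromosome per 2n), then by
P2 depth, then position.

## Synthetic cross (`simulate`)

The generator emulates the validation design: tetraploid, 12 chromosomes ×
5 Mb, 2000 donor-simplex SNPs, a monogenic causal locus at the centre of
chromosome 5, bulks of 23 carriers / 23 non-carriers, mean depth 50×,
substitution error 0.1%. The progeny population defaults to 82 individuals —
the size of the genotyped potato F1 population from which the 23 + 23 bulks
were drawn; a 1:1 segregating phenotype then almost surely supplies both
bulks, which a 46-individual population would fail to do on most draws. The
non-donor SNP classes are not pinned by the reference design and were set
once to mirror it: 2000 recurrent-parent simplex SNPs (reciprocal symmetry),
500 duplex, 200 spurious.

Meiosis: the 2n homologues are partitioned into n random bivalents; each
bivalent transmits one recombinant product with crossovers from a Poisson
process at the configured cM/Mb (default 1; Haldane, no interference). This
construction reproduces the hypergeometric gamete-dosage marginal exactly
(e.g. duplex: carriers paired together w.p. 1/(2n−1) transmit dosage 1;
apart, dosage ~ Bin(2, ½) — totalling the hypergeometric mass), and the tests
confirm it by chi-square goodness of fit. Double reduction and preferential
pairing are not modelled.

Reads: depth ~ Poisson(mean) per site and sample (or fixed, for exact oracle
tests); alt reads ~ Binomial(depth, f(1−e) + (1−f)e/3) with symmetric
substitution error e split over the three non-true bases. Bulk frequency is
the member dosage sum over `bulk_size × ploidy` chromosomes. Spurious sites
surface as alignment-like artifacts with frequency 0.5 in every sample
including the P1 self-alignment (which is otherwise variant-free) — that is
what filter 1 keys on.

What the generator does **not** emulate: mapping bias, repeat-region pileups,
overdispersed (beta-binomial) coverage, indels, genotyping-error structure
correlated across samples. Passing tests therefore demonstrate the
statistical machinery, not robustness to real alignment artifacts beyond the
simple spurious-site model.

## Validation experiments (`experiments`)

Run by the test suite at desk scale (the published experiments used ~100 Gb
of reads per sample and are not reproducible here):

* **Null calibration** — 6 null crosses × 10⁴ simplex SNPs: band exceedance
  0.05 ± 0.01 (see above).
* **Recovery** — 20 seeded replicates of the reference design: the top
  candidate region contains the causal locus in ≥ 18/20 (measured: 20/20);
  the reciprocal-parent orientation yields fewer zero-index SNPs in every
  replicate, pooled chi-square p < 0.001. Per-replicate SNP counts (~1500)
  are two orders below the published experiment, so the chi-square is pooled
  across replicates rather than asserted per seed.
* **Oracle equivalence** — window means vs naive rescan, Fisher p vs
  hypergeometric enumeration, band quantiles vs an independent
  re-simulation with a different seed (within 0.01).

## Numerical conventions

* Quantiles: empirical inverse-CDF (`method="inverted_cdf"`) everywhere.
* All stochastic routines take an explicit integer seed; one
  `numpy.random.Generator` per call, no global state.
* Chromosome ordering: natural sort (chr2 < chr10) in every writer and
  histogram.
* Zero-depth sites are excluded as undefined, never scored as index 0.
* Region intervals in outputs are 1-based inclusive (documented as
  non-standard relative to half-open BED).
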