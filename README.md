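# polyqtlseq

Bulked-segregant QTL mapping for **autopolyploid crops** (tetraploid potato,
hexaploid sweetpotato) from whole-genome allele counts.

## The problem

In an autopolyploid, every locus sits on `ploidy` homologous chromosomes, so an
allele segregates by **dosage**: nulliplex (0 copies), simplex (1), duplex (2),
and so on. Only **simplex** polymorphisms segregate simply in an F1 cross —
simplex × nulliplex gives carriers : non-carriers = 1:1 — which makes them the
workhorse markers of polyploid genetics. The number of whole-genome chromosome
combinations in polyploid F1 progeny is astronomically larger than in a diploid
F2 ((C(4,2)²)¹² ≈ 4.7×10¹⁸ for a 12-chromosome tetraploid vs 3¹² ≈ 5.3×10⁵ for
a diploid), so exhaustive genotype enumeration is hopeless and pooled
(bulked-segregant) sequencing is the pragmatic route to a QTL.

This package implements a polyploid-aware QTL-seq workflow:

1. **SNP index** — at each site, index = alt reads / total reads. A simplex SNP
   converges to 1/ploidy (0.25 tetraploid, ≈0.17 hexaploid) as depth grows.
2. **Consensus reference** — substitute recurrent-parent (P1) majority bases
   (index > 0.5) into the public reference, then drop sites still variant on
   P1 self-alignment as spurious (filter 1).
3. **Simplex filter cascade** — keep sites where both phenotype bulks have
   depth in range and index ≤ the simplex ceiling (filter 2), and where the
   donor parent P2 looks simplex (index within the extraction window, e.g.
   0.10–0.36 at depth ≥ 40 for a tetraploid) while P1 has zero alternate reads
   (filter 3).
4. **Genome scan** — 2 Mb sliding windows (50 kb step) of both bulks' indices
   and of Δ(SNP index) = index(carrier bulk) − index(other bulk), with
   depth-indexed confidence bands simulated under the null of no linkage, and
   per-SNP Fisher's exact tests.
5. **Zero-index cluster scan** — the decisive statistic: donor-simplex SNPs
   whose index in the *non-carrier* bulk is 0 (or ≤0.01, ≤0.02) are counted in
   1 Mb bins; a QTL shows up as a tight cluster of zero-index SNPs, called as
   a candidate region against a Poisson background, with marker-candidate
   SNPs ranked for PCR assay design.

A read-depth design module answers "how deep must I sequence?" by simulating
index distributions per dosage class (at depth 40 a tetraploid duplex site
escapes the simplex window ≈96% of the time, i.e. 95% discrimination
confidence), and a synthetic-cross generator simulates the whole experiment —
dosage-aware meiosis with Haldane crossovers, phenotype bulks, binomial read
sampling — so every pipeline stage is testable without sequencing data.

## Worked example

```python
from polyqtlseq import CrossConfig, PolyploidQtlSeq

config = CrossConfig(seed=3)           # 12 x 5 Mb tetraploid cross, causal on chr05
model = PolyploidQtlSeq.from_simulation(config)
results = model.fit(seed=3)
print(results.summary())
```

prints

```
Polyploid QTL-seq results
============================================================
ploidy: 4   bulk size: 23   carrier bulk: a
filters: depth 40-500, simplex index 0.1-0.36
donor-specific simplex SNPs retained: 1530
genome-wide fraction of SNPs beyond null band: 95%: 0.0660, 99%: 0.0261
candidate regions (zero-index clusters in bulk B): 1
  chr05:1-5000000  zero-index SNPs=32 (hottest bin 10)
top marker candidate: chr05:678389 C>G
```

Reading this: of ~2000 donor-simplex SNPs planted by the simulator, 1530
survive the filter cascade; zero-index SNPs in the non-carrier bulk cluster on
chromosome 5 — the chromosome carrying the planted causal locus (chr05 at
2.5 Mb) — and the single called candidate region contains it. The top
marker-candidate SNP is simplex in P2 (index 0.28), near 0.25 in the carrier
bulk and absent (index 0) from the non-carrier bulk — exactly the profile a
diagnostic PCR marker needs. The genome-wide band-exceedance fractions are
elevated above their nominal 5% / 1% because this run *has* a QTL; on a null
cross they sit at the nominal levels.

`results` also carries `simplex_snps` (per-SNP table with Δ and Fisher p),
`windows`, `band`, `histograms`, `candidate_regions` and `marker_snps`, plus
`plot_scan()` / `plot_clusters()` figure writers.

The same pipeline runs from the shell on TSV allele-count tables
(`chrom pos ref alt depth alt_depth`) or VCFs with AD fields:

```bash
polyqtlseq simulate --outdir sim --seed 3
polyqtlseq filter --ploidy-preset tetraploid_potato \
    --p1 sim/p1.tsv --p2 sim/p2.tsv --bulk-a sim/bulk_a.tsv \
    --bulk-b sim/bulk_b.tsv --p1-self sim/p1_self.tsv --out snps.tsv
polyqtlseq scan --snps snps.tsv --out-prefix scan --seed 3
polyqtlseq cluster --snps snps.tsv --out-prefix clusters
# or everything at once:
polyqtlseq run-all --outdir run --seed 3
```

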