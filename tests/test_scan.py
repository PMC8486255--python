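"""Genome scan: delta index, sliding windows, null bands, Fisher and chi-square tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyqtlseq.scan import (
    CIBand,
    add_delta_snp_index,
    fisher_test,
    fraction_beyond_ci,
    genome_fraction_beyond,
    null_ci,
    reciprocal_comparison,
    sliding_window,
    snp_band_depth,
)


def snp_frame(chrom, pos, a_idx, b_idx, depth=50):
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, list) else [chrom] * n,
            "pos": pos,
            "bulk_a_index": a_idx,
            "bulk_b_index": b_idx,
            "bulk_a_depth": [depth] * n,
            "bulk_b_depth": [depth] * n,
        }
    )


class TestDelta:
    def test_subtraction_and_antisymmetry(self):
        df = snp_frame("chr01", [10, 20], [0.25, 0.1], [0.0, 0.1])
        a = add_delta_snp_index(df, carrier_bulk="a")
        b = add_delta_snp_index(df, carrier_bulk="b")
        assert list(a["delta"]) == pytest.approx([0.25, 0.0])
        assert list(b["delta"]) == pytest.approx([-0.25, 0.0])
        assert a.attrs["carrier_bulk"] == "a"

    def test_bad_orientation(self):
        with pytest.raises(ValueError):
            add_delta_snp_index(snp_frame("chr01", [1], [0.1], [0.1]), carrier_bulk="x")


class TestSlidingWindow:
    def test_single_snp_fills_every_covering_window(self):
        df = add_delta_snp_index(snp_frame("chr01", [3_000_000], [0.3], [0.1]))
        win = sliding_window(df, chrom_lengths={"chr01": 5_000_000})
        covering = win[(win["window_start"] <= 3_000_000) & (win["window_end"] >= 3_000_000)]
        assert (covering["n_snps"] == 1).all()
        assert covering["mean_delta"].unique() == pytest.approx([0.2])
        outside = win[(win["window_end"] < 3_000_000) | (win["window_start"] > 3_000_000)]
        assert (outside["n_snps"] == 0).all()
        assert outside["mean_delta"].isna().all()

    def test_two_snps_average(self):
        df = add_delta_snp_index(snp_frame("chr01", [100, 200], [0.1, 0.3], [0.0, 0.0]))
        win = sliding_window(df, window_bp=1000, step_bp=1000, chrom_lengths={"chr01": 1000})
        assert win["mean_bulk_a_index"].iloc[0] == pytest.approx(0.2)

    def test_unsorted_input_rejected(self):
        df = add_delta_snp_index(snp_frame("chr01", [500, 100], [0.1, 0.2], [0, 0]))
        with pytest.raises(ValueError, match="sorted"):
            sliding_window(df)

    def test_matches_brute_force_rescan(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 2_000_001), size=400, replace=False))
        df = add_delta_snp_index(
            snp_frame("chr01", list(pos), list(rng.random(400)), list(rng.random(400)))
        )
        win = sliding_window(
            df, window_bp=300_000, step_bp=50_000, chrom_lengths={"chr01": 2_000_000}
        )
        for _, w in win.iterrows():
            members = df[(df["pos"] >= w["window_start"]) & (df["pos"] <= w["window_end"])]
            assert w["n_snps"] == len(members)
            if len(members):
                assert w["mean_delta"] == pytest.approx(members["delta"].mean())
                assert w["mean_bulk_a_index"] == pytest.approx(members["bulk_a_index"].mean())
            else:
                assert np.isnan(w["mean_delta"])

    def test_terminal_window_truncated(self):
        df = add_delta_snp_index(snp_frame("chr01", [10], [0.1], [0.1]))
        win = sliding_window(df, window_bp=2_000_000, step_bp=50_000, chrom_lengths={"chr01": 130_000})
        assert win["window_end"].max() == 130_000
        assert (win["window_end"] - win["window_start"] + 1 <= 2_000_000).all()


class TestNullCI:
    def test_bands_nested_and_centered(self):
        band = null_ci(4, 23, depth_grid=[40, 80], n_reps=50_000, seed=1, levels=(0.90, 0.95, 0.99))
        for j, depth in enumerate((40, 80)):
            l90, h90 = band.lo[0, j], band.hi[0, j]
            l95, h95 = band.lo[1, j], band.hi[1, j]
            l99, h99 = band.lo[2, j], band.hi[2, j]
            assert l99 <= l95 <= l90 < 0 < h90 <= h95 <= h99
            # symmetric about 0 up to the delta lattice spacing 1/depth
            assert abs(h95 + l95) <= 1.5 / depth + 0.01

    def test_band_shrinks_with_depth_and_bulk_size(self):
        band = null_ci(4, 23, depth_grid=[30, 300], n_reps=50_000, seed=2, levels=(0.95,))
        assert band.hi[0, 1] < band.hi[0, 0]
        # at high depth the bulk-sampling variance dominates: larger bulks narrow the band
        big = null_ci(4, 500, depth_grid=[200], n_reps=50_000, seed=3, levels=(0.95,))
        small = null_ci(4, 23, depth_grid=[200], n_reps=50_000, seed=3, levels=(0.95,))
        assert (big.hi[0, 0] - big.lo[0, 0]) < (small.hi[0, 0] - small.lo[0, 0])

    def test_width_vanishes_in_large_depth_large_bulk_limit(self):
        wide = null_ci(4, 23, depth_grid=[50], n_reps=20_000, seed=4, levels=(0.95,))
        band = null_ci(4, 1_000, depth_grid=[10_000], n_reps=20_000, seed=4, levels=(0.95,))
        width = band.hi[0, 0] - band.lo[0, 0]
        assert width < 0.05
        assert width < 0.2 * (wide.hi[0, 0] - wide.lo[0, 0])

    def test_matches_independent_resimulation(self):
        """Quantiles agree with a direct re-simulation using a different seed."""
        band = null_ci(4, 23, depth_grid=[50], n_reps=100_000, seed=5, levels=(0.95, 0.99))
        rng = np.random.default_rng(999)
        n = 100_000
        fa = rng.binomial(23, 0.5, n) / 92.0
        fb = rng.binomial(23, 0.5, n) / 92.0
        delta = (rng.binomial(50, fa) - rng.binomial(50, fb)) / 50.0
        for i, lev in enumerate((0.95, 0.99)):
            lo = np.quantile(delta, (1 - lev) / 2, method="inverted_cdf")
            hi = np.quantile(delta, (1 + lev) / 2, method="inverted_cdf")
            assert band.lo[i, 0] == pytest.approx(lo, abs=0.01)
            assert band.hi[i, 0] == pytest.approx(hi, abs=0.01)

    def test_interval_interpolates_and_clamps(self):
        band = CIBand(
            depth_grid=np.array([10, 20]),
            levels=(0.95,),
            lo=np.array([[-0.4, -0.2]]),
            hi=np.array([[0.4, 0.2]]),
            ploidy=4,
            n_bulk=23,
            n_reps=1,
            seed=0,
        )
        lo, hi = band.interval(15, 0.95)
        assert (lo, hi) == (pytest.approx(-0.3), pytest.approx(0.3))
        lo, hi = band.interval(5, 0.95)
        assert (lo, hi) == (pytest.approx(-0.4), pytest.approx(0.4))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            null_ci(4, 23, depth_grid=[])


class TestFisher:
    def test_identical_counts_give_p_one(self):
        assert fisher_test(10, 30, 10, 30) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        """Two-sided p = sum of hypergeometric table probabilities <= observed."""
        alt_a, ref_a, alt_b, ref_b = 0, 40, 20, 20
        n_alt = alt_a + alt_b
        row_a = alt_a + ref_a
        total = row_a + alt_b + ref_b
        probs = [
            stats.hypergeom.pmf(k, total, n_alt, row_a) for k in range(n_alt + 1)
        ]
        p_obs = probs[alt_a]
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert fisher_test(alt_a, ref_a, alt_b, ref_b) == pytest.approx(expected, rel=1e-8)

    def test_doubling_margins_never_increases_p(self):
        for alt_a, ref_a, alt_b, ref_b in [(1, 9, 5, 5), (2, 8, 6, 4), (0, 10, 3, 7)]:
            p1 = fisher_test(alt_a, ref_a, alt_b, ref_b)
            p2 = fisher_test(2 * alt_a, 2 * ref_a, 2 * alt_b, 2 * ref_b)
            assert p2 <= p1 + 1e-12

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            fisher_test(0, 0, 5, 5)


class TestFractionBeyond:
    def test_all_zero_delta_never_beyond(self):
        df = add_delta_snp_index(
            snp_frame("chr01", [100, 200, 300], [0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        )
        band = null_ci(4, 23, depth_grid=[50], n_reps=10_000, seed=6, levels=(0.95,))
        win = fraction_beyond_ci(df, band, 0.95, window_bp=1000, step_bp=1000,
                                 chrom_lengths={"chr01": 300})
        filled = win[win["n_snps"] > 0]
        assert (filled["frac_beyond"] == 0).all()
        assert genome_fraction_beyond(df, band, 0.95) == 0.0

    def test_band_depth_is_harmonic_mean(self):
        df = snp_frame("chr01", [1, 2], [0, 0], [0, 0])
        df.loc[0, "bulk_a_depth"], df.loc[0, "bulk_b_depth"] = 40, 60
        assert snp_band_depth(df)[0] == pytest.approx(48.0)


class TestReciprocal:
    def test_equal_proportions_null(self):
        stat, p = reciprocal_comparison((10, 100), (20, 200))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_published_scale_counts_highly_significant(self):
        _, p = reciprocal_comparison((378, 100_240), (19, 71_083))
        assert p < 0.001

    def test_statistic_matches_textbook_formula(self):
        ca, ta, cb, tb = 8, 40, 2, 50
        stat, _ = reciprocal_comparison((ca, ta), (cb, tb))
        table = np.array([[ca, ta - ca], [cb, tb - cb]], float)
        expected = 0.0
        row = table.sum(1)
        col = table.sum(0)
        for i in range(2):
            for j in range(2):
                e = row[i] * col[j] / table.sum()
                expected += (table[i, j] - e) ** 2 / e
        assert stat == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reciprocal_comparison((5, 0), (1, 10))
        with pytest.raises(ValueError):
            reciprocal_comparison((11, 10), (1, 10))
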