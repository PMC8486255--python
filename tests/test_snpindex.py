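"""SNP index, consensus reference and the three-stage simplex filter cascade."""

import numpy as np
import pandas as pd
import pytest

from conftest import counts
from polyqtlseq.snpindex import (
    FILTER_PRESETS,
    FilterParams,
    _majority_alt,
    build_parent_reference,
    compute_snp_index,
    filter1_spurious,
    filter2_bulk_simplex,
    filter3_p2_simplex,
    run_filters,
)

POTATO = FILTER_PRESETS["tetraploid_potato"]


def test_snp_index_arithmetic_and_zero_depth_exclusion():
    df = counts(
        [
            ("chr01", 10, "A", "T", 40, 10),
            ("chr01", 20, "C", "G", 50, 0),
            ("chr01", 30, "G", "A", 0, 0),
        ]
    )
    out = compute_snp_index(df)
    assert list(out["snp_index"]) == [0.25, 0.0]
    assert 30 not in set(out["pos"])  # undefined ratio excluded, not zero


def test_snp_index_rejects_alt_depth_over_depth():
    with pytest.raises(ValueError):
        compute_snp_index(counts([("chr01", 10, "A", "T", 5, 9)]))


class TestBuildParentReference:
    REF = {"chr01": "AAAAAAAAAA", "chr02": "CCCCC"}

    def test_majority_substituted_and_half_left(self):
        calls = counts(
            [
                ("chr01", 3, "A", "T", 10, 6),  # index 0.6 > 0.5: substituted
                ("chr01", 5, "A", "G", 10, 5),  # exactly 0.5: unchanged
                ("chr02", 2, "C", "T", 10, 9),
            ]
        )
        out = build_parent_reference(self.REF, calls)
        assert out["chr01"] == "AATAAAAAAA"
        assert out["chr02"] == "CTCCC"
        assert all(len(out[c]) == len(self.REF[c]) for c in self.REF)

    def test_empty_calls_identity(self):
        out = build_parent_reference(self.REF, counts([]))
        assert out == self.REF

    def test_position_beyond_end_errors(self):
        calls = counts([("chr02", 99, "C", "T", 10, 9)])
        with pytest.raises(ValueError, match="chr02:99"):
            build_parent_reference(self.REF, calls)


def test_filter1_residual_calls_marked_spurious():
    p1_self = counts(
        [
            ("chr01", 100, "A", "T", 50, 12),  # residual variant: spurious
            ("chr01", 200, "A", "T", 50, 0),  # clean
        ]
    )
    assert filter1_spurious(p1_self) == {("chr01", 100)}
    assert filter1_spurious(counts([])) == set()


@pytest.mark.parametrize(
    "depths,indices,kept",
    [
        ((45, 50), (0.30, 0.10), True),
        ((45, 50), (0.37, 0.10), False),  # 0.37 > 0.36
        ((39, 60), (0.30, 0.10), False),  # 39 < 40
        ((40, 40), (0.36, 0.36), True),  # bounds inclusive
        ((500, 40), (0.30, 0.10), True),  # max depth inclusive
        ((501, 40), (0.30, 0.10), False),
    ],
)
def test_filter2_threshold_edges(depths, indices, kept):
    pos = 1000
    a = counts([("chr01", pos, "A", "T", depths[0], round(indices[0] * depths[0]))])
    b = counts([("chr01", pos, "A", "T", depths[1], round(indices[1] * depths[1]))])
    got = filter2_bulk_simplex(a, b, POTATO)
    assert (("chr01", pos, "T") in got) == kept


def test_filter2_site_in_single_bulk_dropped():
    a = counts([("chr01", 10, "A", "T", 50, 10)])
    b = counts([("chr01", 99, "A", "T", 50, 10)])
    assert filter2_bulk_simplex(a, b, POTATO) == set()


@pytest.mark.parametrize(
    "p2_depth,p2_alt,p1_alt,kept",
    [
        (48, 12, 0, True),  # index 0.25, P1 clean
        (48, 2, 0, False),  # index ~0.04 < 0.10
        (48, 12, 1, False),  # any P1 alternate read disqualifies by default
        (40, 4, 0, True),  # index exactly 0.10 retained (inclusive)
        (39, 10, 0, False),  # depth below threshold
    ],
)
def test_filter3_threshold_edges(p2_depth, p2_alt, p1_alt, kept):
    p2 = counts([("chr01", 5, "A", "T", p2_depth, p2_alt)])
    p1 = counts([("chr01", 5, "A", "T", 52, p1_alt)])
    got = filter3_p2_simplex(p2, p1, POTATO)
    assert (("chr01", 5, "T") in got) == kept


def test_filter3_p1_tolerance_configurable():
    params = FilterParams(40, 500, 0.10, 0.36, p1_zero_max_alt_reads=2)
    p2 = counts([("chr01", 5, "A", "T", 48, 12)])
    p1 = counts([("chr01", 5, "A", "T", 52, 2)])
    assert filter3_p2_simplex(p2, p1, params) == {("chr01", 5, "T")}


def _brute_force_filters(p1_self, p1, p2, bulk_a, bulk_b, params):
    """Independent row-by-row application of all three filter rules."""
    spurious = {
        (r.chrom, r.pos) for r in p1_self.itertuples() if r.alt_depth >= 1
    }
    by_key = lambda df: {(r.chrom, r.pos, r.alt): r for r in df.itertuples() if r.depth > 0}
    kp1, kp2, ka, kb = by_key(p1), by_key(p2), by_key(bulk_a), by_key(bulk_b)
    out = []
    for key in sorted(set(kp1) & set(kp2) & set(ka) & set(kb)):
        chrom, pos, alt = key
        if (chrom, pos) in spurious:
            continue
        ok = True
        for r in (ka[key], kb[key]):
            idx = r.alt_depth / r.depth
            ok &= params.min_depth <= r.depth <= params.max_depth and idx <= params.simplex_max
        r = kp2[key]
        idx = r.alt_depth / r.depth
        ok &= params.min_depth <= r.depth <= params.max_depth
        ok &= params.simplex_min <= idx <= params.simplex_max
        ok &= kp1[key].alt_depth <= params.p1_zero_max_alt_reads
        if ok:
            out.append(key)
    return out


TOY = dict(
    p1_self=counts(
        [
            ("chr01", 700, "G", "A", 45, 0),
            ("chr02", 100, "T", "C", 52, 8),  # spurious
        ]
    ),
    p1=counts(
        [
            ("chr01", 500, "A", "T", 50, 0),
            ("chr01", 700, "G", "A", 45, 0),
            ("chr01", 900, "C", "G", 60, 1),  # P1 not clean
            ("chr02", 100, "T", "C", 52, 0),
            ("chr02", 300, "A", "C", 55, 0),
            ("chr03", 50, "G", "T", 48, 0),
        ]
    ),
    p2=counts(
        [
            ("chr01", 500, "A", "T", 48, 12),  # passes everything
            ("chr01", 700, "G", "A", 44, 11),
            ("chr01", 900, "C", "G", 50, 13),
            ("chr02", 100, "T", "C", 46, 12),  # spurious via filter 1
            ("chr02", 300, "A", "C", 30, 8),  # P2 depth too low
            ("chr03", 50, "G", "T", 48, 30),  # index 0.625: duplex-like
        ]
    ),
    bulk_a=counts(
        [
            ("chr01", 500, "A", "T", 45, 13),
            ("chr01", 700, "G", "A", 39, 5),  # bulk depth below 40
            ("chr01", 900, "C", "G", 50, 10),
            ("chr02", 100, "T", "C", 44, 11),
            ("chr02", 300, "A", "C", 48, 10),
            ("chr03", 50, "G", "T", 52, 14),
        ]
    ),
    bulk_b=counts(
        [
            ("chr01", 500, "A", "T", 50, 2),
            ("chr01", 700, "G", "A", 48, 1),
            ("chr01", 900, "C", "G", 47, 0),
            ("chr02", 100, "T", "C", 41, 0),
            ("chr02", 300, "A", "C", 50, 0),
            ("chr03", 50, "G", "T", 49, 16),
        ]
    ),
)


def test_run_filters_matches_brute_force_on_toy_tables():
    table = run_filters(**TOY, params=POTATO)
    expected = _brute_force_filters(**TOY, params=POTATO)
    assert list(zip(table["chrom"], table["pos"], table["alt"])) == expected
    # exactly one site survives by hand application
    assert expected == [("chr01", 500, "T")]
    row = table.iloc[0]
    assert row["p2_index"] == pytest.approx(12 / 48)
    assert row["bulk_b_index"] == pytest.approx(0.04)


def test_run_filters_empty_inputs():
    empty = counts([])
    table = run_filters(empty, empty, empty, empty, empty, POTATO)
    assert len(table) == 0


def test_filters_idempotent_and_commute():
    """Filters 2 and 3 are set-intersections: order-free and idempotent."""
    k2 = filter2_bulk_simplex(TOY["bulk_a"], TOY["bulk_b"], POTATO)
    k3 = filter3_p2_simplex(TOY["p2"], TOY["p1"], POTATO)
    assert k2 & k3 == k3 & k2
    # idempotence: re-running on the surviving subset changes nothing
    keep = k2 & k3

    def subset(df):
        keys = set(zip(df["chrom"], df["pos"], df["alt"]))
        return df.loc[[k in keep for k in zip(df["chrom"], df["pos"], df["alt"])]]

    k2b = filter2_bulk_simplex(subset(TOY["bulk_a"]), subset(TOY["bulk_b"]), POTATO)
    k3b = filter3_p2_simplex(subset(TOY["p2"]), subset(TOY["p1"]), POTATO)
    assert k2b & k3b == keep


def test_cascade_monotone_on_synthetic_cross(small_cross):
    config, tables, truth = small_cross
    table = run_filters(
        tables["p1_self"], tables["p1"], tables["p2"], tables["bulk_a"], tables["bulk_b"], POTATO
    )
    retained = set(zip(table["chrom"], table["pos"]))
    assert retained <= set(zip(tables["p2"]["chrom"], tables["p2"]["pos"]))
    assert len(table) > 0


def test_retained_snps_are_truly_p2_simplex(small_cross):
    """At ~50x depth, at least 95% of retained SNPs carry the true donor-simplex label."""
    config, tables, truth = small_cross
    table = run_filters(
        tables["p1_self"], tables["p1"], tables["p2"], tables["bulk_a"], tables["bulk_b"], POTATO
    )
    labels = truth.snps.set_index(["chrom", "pos"])["snp_class"]
    got = labels.loc[list(zip(table["chrom"], table["pos"]))]
    assert (got == "p2_simplex").mean() >= 0.95


def test_duplex_contamination_matches_binomial_leakage(small_cross):
    """Duplex leakage through the P2 index window agrees with the exact binomial tail."""
    from scipy import stats

    config, tables, truth = small_cross
    dup = truth.snps["snp_class"] == "duplex"
    p2 = tables["p2"].loc[dup.to_numpy()]
    p2 = p2.loc[(p2["depth"] >= 40) & (p2["depth"] <= 500)]
    idx = p2["alt_depth"] / p2["depth"]
    observed = ((idx >= 0.10) & (idx <= 0.36)).sum()
    # exact per-site probability at each site's own depth
    lo = np.ceil(0.10 * p2["depth"] - 1e-9)
    hi = np.floor(0.36 * p2["depth"] + 1e-9)
    p = stats.binom.cdf(hi, p2["depth"], 0.5) - stats.binom.cdf(lo - 1, p2["depth"], 0.5)
    expected = p.sum()
    sd = np.sqrt((p * (1 - p)).sum())
    assert abs(observed - expected) <= 4 * sd + 2


def test_multi_alt_majority_rule_and_tie_drop():
    p2 = counts(
        [
            ("chr01", 5, "A", "T", 48, 12),
            ("chr01", 5, "A", "G", 48, 3),  # minority alternate discarded
            ("chr02", 9, "C", "T", 50, 6),
            ("chr02", 9, "C", "A", 50, 6),  # exact tie: site dropped
        ]
    )
    p1 = counts([("chr01", 5, "A", "T", 52, 0), ("chr02", 9, "C", "T", 55, 0)])
    got = filter3_p2_simplex(_majority_alt(p2), p1, POTATO)
    assert got == {("chr01", 5, "T")}
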