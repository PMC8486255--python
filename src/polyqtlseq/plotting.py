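"""Figure-style plots: sliding-window scan panels and zero-index cluster histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .snpindex import _natural_key


def plot_scan(results, path: str | Path, level: float | None = None) -> None:
    """One row per chromosome: bulk SNP-index means, delta with null band, exceedance."""
    windows = results.windows
    chroms = sorted(windows["chrom"].unique(), key=_natural_key)
    if level is None:
        level = results.band.levels[0]
    fig, axes = plt.subplots(
        len(chroms), 3, figsize=(12, 1.8 * len(chroms)), squeeze=False, sharex="col"
    )
    for i, chrom in enumerate(chroms):
        w = windows.loc[windows["chrom"] == chrom]
        mid = (w["window_start"] + w["window_end"]) / 2e6
        ax = axes[i][0]
        ax.plot(mid, w["mean_bulk_a_index"], lw=0.8, label="bulk A")
        ax.plot(mid, w["mean_bulk_b_index"], lw=0.8, label="bulk B")
        ax.set_ylim(0, 1)
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
        ax = axes[i][1]
        ax.plot(mid, w["mean_delta"], color="red", lw=0.8)
        # depth-averaged band rendered flat per chromosome midline
        lo, hi = results.band.interval(float(results.band.depth_grid.mean()), level)
        ax.axhline(float(lo), color="green", lw=0.6)
        ax.axhline(float(hi), color="green", lw=0.6)
        ax.set_ylim(-1, 1)
        ax = axes[i][2]
        col = f"frac_beyond_{level:g}"
        if col in w:
            ax.plot(mid, w[col], color="purple", lw=0.8)
        ax.set_ylim(0, 1)
    axes[0][0].set_title("bulk SNP index")
    axes[0][1].set_title("delta SNP index")
    axes[0][2].set_title(f"fraction beyond {level:.0%} band")
    axes[0][0].legend(fontsize=6)
    for ax in axes[-1]:
        ax.set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_clusters(results, path: str | Path) -> None:
    """Stacked per-Mb histogram of low-index SNP classes, one panel per chromosome."""
    hist = results.histograms
    chroms = sorted(hist["chrom"].unique(), key=_natural_key)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 1.2 * len(chroms)), squeeze=False)
    for i, chrom in enumerate(chroms):
        h = hist.loc[hist["chrom"] == chrom]
        x = h["bin_start"] / 1e6
        ax = axes[i][0]
        ax.bar(x, h["n_zero"], width=0.9, color="black", label="index = 0")
        ax.bar(x, h["n_le_t1"], width=0.9, bottom=h["n_zero"], color="dimgray", label="<= 0.01")
        ax.bar(
            x,
            h["n_le_t2"],
            width=0.9,
            bottom=h["n_zero"] + h["n_le_t1"],
            color="lightgray",
            label="<= 0.02",
        )
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
    axes[0][0].legend(fontsize=6)
    axes[-1][0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
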