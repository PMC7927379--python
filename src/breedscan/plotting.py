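"""Plotting helpers: Manhattan plots, embedding scatters, SNP density."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .structure import EmbeddingResult

__all__ = ["manhattan_plot", "embedding_plot", "density_plot"]


def manhattan_plot(
    table: pd.DataFrame, path: str | Path, title: str = "", alpha: float = 0.01
) -> None:
    """Per-locus -log10(p) against the genome, alternating colors by chromosome."""
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, block) in enumerate(table.groupby("chrom", sort=False)):
        x = block["pos"].to_numpy() + offset
        ax.scatter(x, block["neg_log10_p"], s=4, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + block["pos"].max() / 2)
        labels.append(str(chrom))
        offset += block["pos"].max()
    ax.axhline(-np.log10(alpha), color="grey", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embedding_plot(
    result: EmbeddingResult, samples: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """First two embedding axes, colored by breed."""
    fig, ax = plt.subplots(figsize=(6, 5))
    coords = result.coordinates
    for breed in pd.unique(samples["breed"]):
        mask = (samples["breed"] == breed).to_numpy()
        ax.scatter(coords[mask, 0], coords[mask, 1], s=12, label=breed)
    if result.variance_fraction.size >= 2:
        ax.set_xlabel(f"axis 1 ({100 * result.variance_fraction[0]:.2f}%)")
        ax.set_ylabel(f"axis 2 ({100 * result.variance_fraction[1]:.2f}%)")
    else:
        ax.set_xlabel("axis 1")
        ax.set_ylabel("axis 2")
    ax.legend(fontsize=6, ncol=2, markerscale=0.8)
    ax.set_title(title or result.method)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def density_plot(density: pd.DataFrame, path: str | Path, window_bp: int = 400_000) -> None:
    """SNP counts per window along each chromosome."""
    chroms = list(pd.unique(density["chrom"]))
    fig, ax = plt.subplots(figsize=(10, 3))
    for i, chrom in enumerate(chroms):
        block = density[density["chrom"] == chrom]
        ax.bar(
            block["window_start"] / 1e6 + i * 0.0,
            block["count"],
            width=window_bp / 1e6,
            bottom=i * 0,
            alpha=0.6,
            label=str(chrom) if len(chroms) <= 20 else None,
        )
    ax.set_xlabel("window start (Mb)")
    ax.set_ylabel(f"SNPs per {window_bp // 1000} kb")
    if len(chroms) <= 20:
        ax.legend(fontsize=6, ncol=4)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
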