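"""Optional figure output (requires matplotlib).

Mirrors the figures the analysis is usually presented with: a dot plot
of permutation enrichments (colour = direction of correlation, size =
significance tier), average binding profiles, the two-knockdown log2FC
heatmap with a blue-white-red palette, and violin plots of expression
change per differential class.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


#: aquamarine = positive correlation, red = negative, grey = untested
DIRECTION_COLOURS = {"positive": "#7fffd4", "negative": "#d62728", "none": "#bbbbbb"}
TIER_SIZES = {"none": 20.0, "significant": 90.0, "highly-significant": 240.0}


def plot_permutation_dotplot(results: Sequence, path: str | Path) -> None:
    """One circle per antibody x peak-class x partition."""
    plt = _pyplot()
    rows = sorted({(r.antibody, r.peak_class) for r in results})
    cols = sorted({r.partition for r in results})
    fig, ax = plt.subplots(
        figsize=(2.0 + 1.2 * len(cols), 1.0 + 0.35 * len(rows))
    )
    for r in results:
        y = rows.index((r.antibody, r.peak_class))
        x = cols.index(r.partition)
        colour = DIRECTION_COLOURS[r.direction if r.tier != "none" else "none"]
        ax.scatter(x, y, s=TIER_SIZES[r.tier], c=colour, edgecolors="black",
                   linewidths=0.4, zorder=3)
    ax.set_xticks(range(len(cols)), cols)
    ax.set_yticks(range(len(rows)), [f"{a} {c}" for a, c in rows], fontsize=7)
    ax.set_xlim(-0.5, len(cols) - 0.5)
    ax.invert_yaxis()
    ax.set_title("binding-pattern enrichment vs shuffle null", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile(profile, path: str | Path, title: str = "") -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.offsets, profile.mean, color="#c0c0c0", lw=0.8,
            label="raw mean")
    ax.plot(profile.offsets, profile.smoothed, color="#1f77b4", lw=1.8,
            label="LOESS")
    ax.set_xlabel("offset from peak centre (bp)")
    ax.set_ylabel("mean coverage")
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Gene x condition log2FC matrix, blue-white-red, no clustering."""
    plt = _pyplot()
    vals = matrix.to_numpy(dtype=float)
    lim = max(1.0, np.abs(vals).max()) if vals.size else 1.0
    fig, ax = plt.subplots(figsize=(3, 6))
    im = ax.imshow(vals, aspect="auto", cmap="bwr", vmin=-lim, vmax=lim,
                   interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, fontsize=7,
                  rotation=30, ha="right")
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2FC (0-substituted)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_class_violin(
    de_by_class: Mapping[str, Sequence[float]], path: str | Path,
    ylabel: str = "log2FC",
) -> None:
    """Violin of expression change per differential class."""
    plt = _pyplot()
    labels = [k for k, v in de_by_class.items() if len(v)]
    data = [np.asarray(de_by_class[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(1.2 + 1.0 * len(labels), 3.2))
    if data:
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
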