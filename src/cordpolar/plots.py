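"""Rose diagrams and FDR heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def rose_figure(rose_table: pd.DataFrame, title: str = ""):
    """Polar bar chart from a rose-histogram table (bar length = % cells)."""
    theta = np.deg2rad(rose_table["bin_start_deg"].to_numpy())
    width = np.deg2rad(rose_table["bin_end_deg"].to_numpy()
                       - rose_table["bin_start_deg"].to_numpy())
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.bar(theta, rose_table["percent"].to_numpy(), width=width,
           align="edge", edgecolor="k", linewidth=0.3)
    ax.set_title(title)
    return fig


def fdr_heatmap(pairwise: pd.DataFrame, cell_class: str):
    """Genotype x genotype heatmap of BH-adjusted q-values for one class."""
    sub = pairwise[pairwise["cell_class"] == cell_class]
    names = sorted(set(sub["group_a"]) | set(sub["group_b"]))
    mat = np.full((len(names), len(names)), np.nan)
    for _, row in sub.iterrows():
        i, j = names.index(row["group_a"]), names.index(row["group_b"])
        mat[i, j] = mat[j, i] = row["q"]
    fig, ax = plt.subplots()
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis_r")
    ax.set_xticks(range(len(names)), names, rotation=45)
    ax.set_yticks(range(len(names)), names)
    ax.set_title(f"{cell_class}: pairwise FDR (q)")
    fig.colorbar(im, ax=ax, label="q")
    return fig


def mean_ci_figure(circular_summary: pd.DataFrame, cell_class: str):
    """Mean angle with 95% CI per genotype, on a polar axis."""
    sub = circular_summary[circular_summary["cell_class"] == cell_class]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for k, (_, row) in enumerate(sub.iterrows()):
        r = 1.0 + 0.1 * k
        mean = np.deg2rad(row["circ_mean_deg"])
        lo, hi = np.deg2rad([row["ci_low_deg"], row["ci_high_deg"]])
        if hi < lo:
            hi += 2 * np.pi
        arc = np.linspace(lo, hi, 50)
        ax.plot(arc, np.full_like(arc, r), lw=1.5)
        ax.plot([mean], [r], "o", label=str(row["genotype"]))
    ax.set_rticks([])
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize=8)
    ax.set_title(f"{cell_class}: mean angle and 95% CI")
    return fig
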