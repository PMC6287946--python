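"""Figure helpers for the analysis scripts (matplotlib, non-interactive)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .trajectories import Embedding, HeatmapView


def heatmap_pair(view: HeatmapView, path: str | Path, max_rows: int = 2000) -> None:
    """Side-by-side row-max and absolute heatmaps with identical row order."""
    step = max(1, len(view.order) // max_rows)
    rm = view.row_max.iloc[::step]
    ab = view.absolute.iloc[::step]
    fig, axes = plt.subplots(1, 2, figsize=(8, 6), sharey=True)
    for ax, mat, title, vmax in (
        (axes[0], rm, "row-max normalized", 1.0),
        (axes[1], ab, "absolute (control-normalized)", np.quantile(ab, 0.99)),
    ):
        im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmax=vmax)
        ax.set_title(title, fontsize=9)
        ax.set_xticks(range(len(mat.columns)))
        ax.set_xticklabels([f"{c:g}" for c in mat.columns], fontsize=6)
        ax.set_xlabel("time (min)")
        fig.colorbar(im, ax=ax, shrink=0.6)
    axes[0].set_ylabel("binding sites (time-of-max blocks)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def embedding_scatter(
    embedding: Embedding,
    color: pd.Series,
    path: str | Path,
    title: str = "",
    log_color: bool = False,
) -> None:
    """t-SNE map colored by a per-site quantity (class or FDR)."""
    xy = embedding.coords
    fig, ax = plt.subplots(figsize=(5, 4.5))
    c = color.reindex(xy.index)
    if c.dtype == object:
        for lab, grp in xy.groupby(c):
            ax.scatter(grp["x"], grp["y"], s=4, label=str(lab), alpha=0.6)
        ax.legend(markerscale=3, fontsize=7)
    else:
        vals = -np.log10(np.maximum(c.astype(float), 1e-30)) if log_color else c
        sc = ax.scatter(xy["x"], xy["y"], c=vals, s=4, cmap="viridis", alpha=0.7)
        fig.colorbar(sc, ax=ax, shrink=0.8,
                     label="-log10 FDR" if log_color else c.name)
    ax.set_title(title or f"t-SNE (perplexity {embedding.perplexity:g})", fontsize=9)
    ax.set_xticks([]), ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def profile_plot(profiles: dict[str, pd.DataFrame], path: str | Path,
                 ylabel: str = "normalized occupancy") -> None:
    """Mean +/- SD time profiles for a few sites or class averages."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for label, tab in profiles.items():
        ax.errorbar(tab.index, tab["mean"], yerr=tab["sd"], marker="o",
                    capsize=2, label=label)
    ax.set_xlabel("time after stimulation (min)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
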