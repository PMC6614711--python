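"""Minimal plotting helpers (correlation heatmap, PCoA scatter)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def correlation_heatmap(result, path, alpha: float = 0.01) -> None:
    """Render a taxa x parameters correlation heatmap with significance stars
    to SVG/PNG (format chosen by the file extension)."""
    corr = result.correlations
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.45 * corr.shape[1] + 2), max(3.0, 0.3 * corr.shape[0]))
    )
    im = ax.imshow(corr.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(corr.shape[1]), corr.columns, rotation=90, fontsize=7)
    labels = [f"{t} [{result.clusters[t]}]" if result.clusters is not None
              else str(t) for t in corr.index]
    ax.set_yticks(range(corr.shape[0]), labels, fontsize=7)
    stars = result.stars(alpha)
    for i in range(corr.shape[0]):
        for j in range(corr.shape[1]):
            if bool(stars.iloc[i, j]):
                ax.text(j, i, "*", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pcoa_scatter(ordination, meta, path, color_by: str = "reactor") -> None:
    """Scatter the first two principal coordinates, coloured by metadata."""
    coords = ordination.coordinates
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = meta.loc[coords.index, color_by]
    for g in np.unique(groups):
        sel = groups == g
        ax.scatter(coords.loc[sel, "PCo1"], coords.loc[sel, "PCo2"],
                   label=str(g), s=14)
    expl = ordination.explained_fraction
    ax.set_xlabel(f"PCo1 ({expl[0]:.1%})" if len(expl) > 0 else "PCo1")
    ax.set_ylabel(f"PCo2 ({expl[1]:.1%})" if len(expl) > 1 else "PCo2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
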