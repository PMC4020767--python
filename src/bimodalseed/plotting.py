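"""Landscape and ECDF figures."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ecdf import ClassDistribution
from .enrichment import EnrichmentLandscape

_HIGHLIGHT_COLORS = {"CS": "crimson", "CS+1": "seagreen", "IS": "royalblue", "IS+1": "purple"}


def plot_landscapes(
    highlighted: Mapping[str, EnrichmentLandscape],
    background: Sequence[EnrichmentLandscape] = (),
    path: str | Path | None = None,
    title: str = "word enrichment landscape",
):
    """Signed -log10 enrichment curves over leading bins of the ranked list.

    ``highlighted`` maps a seed label (CS, CS+1, IS, IS+1, ...) to its
    landscape; ``background`` curves are drawn in light grey.
    """
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for lc in background:
        ax.plot(lc.bin_edges, lc.signed_logp, color="0.8", lw=0.6, zorder=1)
    for label, lc in highlighted.items():
        color = _HIGHLIGHT_COLORS.get(label)
        ax.plot(
            lc.bin_edges,
            lc.signed_logp,
            lw=1.8,
            label=f"{label} ({lc.word})",
            color=color,
            zorder=2,
        )
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("leading genes (most down-regulated first)")
    ax.set_ylabel("signed $-\\log_{10} p$ (hypergeometric)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_ecdfs(
    distributions: Mapping[str, ClassDistribution],
    path: str | Path | None = None,
    title: str = "log2 fold change by seed class",
):
    """Grimson-style ECDF curves of log2 fold changes for the four classes."""
    colors = {
        "CS_only": "crimson",
        "IS_only": "royalblue",
        "both": "purple",
        "neither": "0.4",
    }
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for cls, dist in distributions.items():
        if dist.n == 0:
            continue
        ax.step(
            dist.values,
            (1 + np.arange(dist.n)) / dist.n,
            where="post",
            label=f"{cls} (n={dist.n})",
            color=colors.get(cls),
        )
    ax.set_xlabel("log2 fold change (treatment - control)")
    ax.set_ylabel("cumulative fraction")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
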