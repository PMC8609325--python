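"""Plot exports: micro-fraction / interaction heat maps and P(s) curves."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from microchrom.hic import PsCurve


def plot_heatmap(table: pd.DataFrame, path, title: str = "",
                 cmap: str = "viridis", log: bool = False) -> None:
    """Render a square matrix (fractions or mean interactions) to SVG/PNG."""
    fig, ax = plt.subplots(figsize=(6, 5))
    values = table.to_numpy(dtype=float)
    if log:
        values = np.log10(values, where=values > 0,
                          out=np.full_like(values, np.nan))
    im = ax.imshow(values, cmap=cmap, aspect="auto")
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=90,
                  fontsize=7)
    ax.set_yticks(range(len(table.index)), table.index, fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ps(curves: Mapping[str, PsCurve] | Sequence[PsCurve], path,
            title: str = "P(s) by chromosome class") -> None:
    """Log-log distance-decay plot, one line per chromosome class."""
    if isinstance(curves, Mapping):
        curves = list(curves.values())
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for c in curves:
        ok = np.isfinite(c.p) & (c.p > 0) & (c.n_pairs > 0)
        ax.loglog(c.midpoints[ok], c.p[ok], marker="o", ms=3, label=c.label)
    ax.set_xlabel("genomic separation s (bp)")
    ax.set_ylabel("contact probability P(s)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
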