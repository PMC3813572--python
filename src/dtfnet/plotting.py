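"""Minimal matrix heat-map export for connectivity and mixing matrices."""
from __future__ import annotations

import numpy as np


def plot_matrix(values, labels, path=None, title: str = "",
                xlabel: str = "source", ylabel: str = "target", ax=None):
    """Heat map of a (target, source) matrix with labelled axes.

    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(0.45 * len(labels) + 2,) * 2)
    im = ax.imshow(values, cmap="viridis", aspect="equal")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
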