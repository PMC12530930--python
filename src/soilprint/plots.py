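"""Optional figure output: score scatter plots and dendrograms.

Matplotlib is imported lazily so headless pipeline runs without figures
never touch it.
"""

from __future__ import annotations

import numpy as np


def _pyplot():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_scores(scores: np.ndarray, labels, path, title: str = "",
                explained_pct=None) -> None:
    """2-D score scatter (first two components), one colour per group."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for group in dict.fromkeys(labels):
        sel = labels == group
        ax.scatter(scores[sel, 0], scores[sel, 1], label=str(group), s=30)
    if explained_pct is not None:
        ax.set_xlabel(f"t1 ({explained_pct[0]:.1f}%)")
        ax.set_ylabel(f"t2 ({explained_pct[1]:.1f}%)")
    else:
        ax.set_xlabel("t1")
        ax.set_ylabel("t2")
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dendrogram(linkage_matrix: np.ndarray, sample_ids, path,
                    title: str = "") -> None:
    """Dendrogram of an HCA merge tree."""
    from scipy.cluster import hierarchy

    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(7, 4))
    hierarchy.dendrogram(linkage_matrix, labels=list(sample_ids), ax=ax,
                         leaf_rotation=90)
    ax.set_ylabel("merge distance")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
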