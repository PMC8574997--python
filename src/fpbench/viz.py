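"""Minimal plotting helpers: a similarity heatmap and a class-frequency bar chart."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_similarity_heatmap(
    sim: np.ndarray,
    names: Sequence[str],
    order: Sequence[int] | None = None,
    out: str | Path | None = None,
):
    """Heatmap of a pairwise fingerprint similarity matrix, optionally reordered."""
    idx = list(order) if order is not None else list(range(len(names)))
    m = np.asarray(sim)[np.ix_(idx, idx)]
    labels = [names[i] for i in idx]
    fig, ax = plt.subplots(figsize=(1.0 + 0.5 * len(labels), 1.0 + 0.5 * len(labels)))
    im = ax.imshow(m, vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90)
    ax.set_yticks(range(len(labels)), labels)
    fig.colorbar(im, ax=ax, label="CKA")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_class_frequencies(labels: Sequence, out: str | Path | None = None):
    """Bar chart of compound counts per class label."""
    values, counts = np.unique(np.asarray(labels), return_counts=True)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar([str(v) for v in values], counts)
    ax.set_xlabel("class")
    ax.set_ylabel("compounds")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
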