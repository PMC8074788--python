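"""Cosmetic plots: marker detection heatmaps and PCA scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .multivariate import PCAResult  # noqa: E402
from .psm_model import DetectionMatrix  # noqa: E402


def detection_heatmap(dm: DetectionMatrix, path, drop_empty: bool = True) -> None:
    """PSM-count heatmap (markers x samples), white = undetected."""
    values = dm.values
    if drop_empty:
        values = values.loc[values.sum(axis=1) > 0]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(values.columns)), max(4, 0.12 * len(values))))
    im = ax.imshow(values.to_numpy(dtype=float), aspect="auto", cmap="Greys")
    ax.set_xticks(range(len(values.columns)), values.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(values)), values.index, fontsize=4)
    fig.colorbar(im, ax=ax, label=dm.value_kind)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(result: PCAResult, path, labels=None) -> None:
    """PC1/PC2 scatter of sample scores, optionally coloured by label."""
    fig, ax = plt.subplots(figsize=(6, 5))
    xy = result.scores[:, :2]
    if labels is None:
        ax.scatter(xy[:, 0], xy[:, 1], s=25)
    else:
        labels = np.asarray(labels)
        for lab in dict.fromkeys(labels):
            sel = labels == lab
            ax.scatter(xy[sel, 0], xy[sel, 1], s=25, label=str(lab))
        ax.legend(fontsize=7)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
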