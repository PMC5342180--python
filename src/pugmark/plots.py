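"""Simple diagnostic figures: dendrogram, holdback validation, sex scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .sexing import SexModel

__all__ = ["plot_dendrogram", "plot_holdback", "plot_sex_scatter"]


def plot_dendrogram(
    linkage: np.ndarray,
    labels: list[str],
    path: str | Path,
    threshold: float | None = None,
) -> None:
    """Trail dendrogram with an optional horizontal cut line."""
    fig, ax = plt.subplots(figsize=(max(6.0, 0.25 * len(labels)), 4.5))
    hierarchy.dendrogram(
        linkage, labels=labels, ax=ax, leaf_rotation=90, color_threshold=threshold
    )
    if threshold is not None:
        ax.axhline(threshold, color="red", linestyle="--", linewidth=1,
                   label=f"threshold {threshold:.3g}")
        ax.legend(loc="upper right")
    ax.set_ylabel("Ward distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_holdback(summary: pd.DataFrame, path: str | Path) -> None:
    """Test-set size vs expected (red), per-iteration predicted (black)
    and mean predicted (blue)."""
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    sizes = summary["size"].to_numpy()
    ax.plot(np.unique(sizes), np.unique(sizes), "r-", label="expected")
    ax.scatter(sizes, summary["predicted"], color="black", s=14, zorder=3,
               label="predicted (iteration)")
    means = summary.drop_duplicates("size")
    ax.plot(means["size"], means["mean_predicted"], "b-o", markersize=4,
            label="mean predicted")
    ax.set_xlabel("test-set size (animals)")
    ax.set_ylabel("number of individuals")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sex_scatter(model: SexModel, table: pd.DataFrame, path: str | Path) -> None:
    """Footprints on the discriminant axis vs the leading residual axis.

    Two classes give a single discriminant direction; the y axis is the
    first principal component of the selected variables after removing the
    discriminant direction, so the cloud is spread in two dimensions.
    """
    X = table[model.variables].to_numpy(float)
    scores = model.decision_scores(X)
    w = model.weights / np.linalg.norm(model.weights)
    resid = (X - X.mean(axis=0)) - np.outer((X - X.mean(axis=0)) @ w, w)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    y = resid @ vt[0]
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    sexes = table["sex"].astype(str).to_numpy() if "sex" in table.columns else None
    styles = {"F": ("red", "*"), "M": ("blue", "*")}
    if sexes is not None and set(np.unique(sexes)) & {"F", "M"}:
        for sex, (color, marker) in styles.items():
            m = sexes == sex
            if m.any():
                ax.scatter(scores[m], y[m], c=color, marker=marker, s=30, label=sex)
        unk = ~np.isin(sexes, ["F", "M"])
        if unk.any():
            ax.scatter(scores[unk], y[unk], c="black", marker="s", s=24,
                       label="unknown")
        ax.legend()
    else:
        ax.scatter(scores, y, c="black", s=20)
    ax.axvline(0.0, color="grey", linewidth=0.8, linestyle=":")
    ax.set_xlabel("discriminant score (male > 0)")
    ax.set_ylabel("residual axis 1")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
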