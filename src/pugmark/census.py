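"""Individual census from the pairwise trail distance matrix.

Trails are agglomerated with Ward's minimum-variance criterion applied to
the precomputed centroid distances (Lance-Williams update); cutting the
dendrogram at a threshold yields the predicted number of individuals.  The
threshold is tuned on training data to maximize trail-placement accuracy,
and a bootstrap profile expresses the relative likelihood of neighbouring
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .pairwise import AlgorithmConfig, pairwise_matrix

__all__ = [
    "CensusResult",
    "ward_cluster",
    "estimate_individuals",
    "tune_threshold",
    "trail_placement_accuracy",
    "likelihood_profile",
    "linkage_to_newick",
]


@dataclass
class CensusResult:
    """Ward linkage, threshold, assignment and the estimated head count."""

    linkage: np.ndarray
    threshold: float
    assignment: pd.Series          # trail_id -> cluster label (1-based)
    estimated_n_individuals: int
    relative_likelihood: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "estimated_n_individuals": int(self.estimated_n_individuals),
            "assignment": {str(k): int(v) for k, v in self.assignment.items()},
            "relative_likelihood": {
                str(k): float(v) for k, v in sorted(self.relative_likelihood.items())
            },
            "linkage": [[float(x) for x in row] for row in self.linkage],
        }


def _check_distance_matrix(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(D)):
        bad = np.argwhere(np.isnan(np.triu(D, 1)))
        pairs = ", ".join(f"({i},{j})" for i, j in bad[:20])
        raise ValueError(f"NaN entries in distance matrix at pairs: {pairs}")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")
    return D


def ward_cluster(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward linkage over a precomputed trail dissimilarity matrix."""
    D = _check_distance_matrix(dist)
    if D.shape[0] < 2:
        raise ValueError("need at least 2 trails to cluster")
    return hierarchy.linkage(squareform(D, checks=False), method="ward")


def estimate_individuals(
    linkage: np.ndarray,
    threshold: float,
    labels: list[str] | None = None,
) -> tuple[int, pd.Series]:
    """Cut the dendrogram: clusters are components joined at or below the
    threshold; the cluster count is the estimated number of individuals."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    flat = hierarchy.fcluster(linkage, t=threshold, criterion="distance")
    n_leaves = linkage.shape[0] + 1
    if labels is None:
        labels = [str(i) for i in range(n_leaves)]
    assignment = pd.Series(flat, index=labels, name="cluster")
    return int(flat.max()), assignment


def trail_placement_accuracy(
    assignment: pd.Series | dict, truth: pd.Series | dict
) -> float:
    """Percent of trails placed in the cluster matched to their true animal.

    Clusters are matched one-to-one to animals by maximum-cardinality
    optimal assignment (Hungarian algorithm on the contingency table), so
    the metric is invariant to cluster relabeling.
    """
    assignment = pd.Series(assignment)
    truth = pd.Series(truth)
    if set(assignment.index) != set(truth.index):
        raise ValueError("assignment and truth must cover the same trails")
    truth = truth.loc[assignment.index]
    tab = pd.crosstab(assignment, truth)
    cost = -tab.to_numpy()
    rows, cols = linear_sum_assignment(cost)
    matched = int(-cost[rows, cols].sum())
    return 100.0 * matched / len(assignment)


def tune_threshold(
    linkage: np.ndarray,
    truth: pd.Series | dict,
    labels: list[str],
    grid: np.ndarray | None = None,
) -> float:
    """Grid-search the cut height maximizing trail-placement accuracy.

    Ties resolve to the smallest threshold.  The default grid is built from
    the midpoints between consecutive merge heights (plus the extremes), the
    only places the partition can change.
    """
    truth = pd.Series(truth)
    heights = np.sort(linkage[:, 2])
    if grid is None:
        uniq = np.unique(heights)
        mids = 0.5 * (uniq[:-1] + uniq[1:])
        grid = np.concatenate([[0.0], mids, [uniq[-1] * 1.05 + 1e-12]])
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    best_t = None
    best_acc = -np.inf
    for t in np.sort(grid):
        _, assignment = estimate_individuals(linkage, float(t), labels)
        acc = trail_placement_accuracy(assignment, truth)
        if acc > best_acc + 1e-12:
            best_acc = acc
            best_t = float(t)
    return best_t


def likelihood_profile(
    table: pd.DataFrame,
    config: AlgorithmConfig,
    threshold: float,
    n_bootstrap: int = 200,
    seed: int = 0,
    rcv_table: pd.DataFrame | None = None,
) -> dict[int, float]:
    """Bootstrap relative likelihood of each candidate individual count.

    Footprints are resampled with replacement within each trail; the
    pairwise matrix and the clustering are recomputed per replicate and the
    predicted counts tabulated.  The profile is each count's frequency
    divided by the modal count's frequency, so the mode maps to 1.0.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    rng = np.random.default_rng(seed)
    groups = {tid: sub for tid, sub in table.groupby("trail_id")}
    counts: dict[int, int] = {}
    for _ in range(n_bootstrap):
        parts = []
        for tid, sub in groups.items():
            idx = rng.integers(0, len(sub), size=len(sub))
            parts.append(sub.iloc[idx])
        boot = pd.concat(parts, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mats = pairwise_matrix(boot, config, rcv_table=rcv_table)
        if mats.distances.isna().any().any():
            continue
        Z = ward_cluster(mats.distances)
        k, _ = estimate_individuals(Z, threshold, list(mats.distances.index))
        counts[k] = counts.get(k, 0) + 1
    if not counts:
        raise RuntimeError("all bootstrap replicates failed")
    peak = max(counts.values())
    return {k: v / peak for k, v in sorted(counts.items())}


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage table as a Newick tree (heights as distances)."""
    tree = hierarchy.to_tree(linkage)

    def build(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
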