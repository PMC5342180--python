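"""Sequential holdback validation of the individual-census pipeline.

Animals (not trails) are randomly apportioned into training and test sets.
The Ward cut threshold is tuned on the training animals' trails, the test
animals' trails are clustered with the reference-centroid group drawn from
the training rows only (no leakage), and the predicted individual count is
scored against the true number of test animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import estimate_individuals, trail_placement_accuracy, tune_threshold, ward_cluster
from .pairwise import MIN_TRAIL_PRINTS, AlgorithmConfig, pairwise_matrix

__all__ = ["HoldbackIteration", "HoldbackReport", "holdback_trial", "summarize_holdback"]


@dataclass
class HoldbackIteration:
    test_size: int
    iteration: int
    test_animals: list[str]
    true_count: int
    predicted_count: int
    threshold: float
    accuracy: float     # 100 - 100*|pred - true|/true


@dataclass
class HoldbackReport:
    iterations: list[HoldbackIteration]
    config: AlgorithmConfig
    seed: int

    def mean_accuracy(self, test_size: int | None = None) -> float:
        rows = [
            it for it in self.iterations
            if test_size is None or it.test_size == test_size
        ]
        if not rows:
            raise ValueError("no iterations match")
        return float(np.mean([it.accuracy for it in rows]))


def _usable_trails(table: pd.DataFrame) -> pd.Series:
    counts = table.groupby("trail_id").size()
    return counts[counts >= MIN_TRAIL_PRINTS]


def _truth_for(table: pd.DataFrame, trails: list[str]) -> pd.Series:
    m = table.drop_duplicates("trail_id").set_index("trail_id")["animal_id"]
    return m.loc[trails]


def _cluster_trails(
    table: pd.DataFrame,
    config: AlgorithmConfig,
    rcv_table: pd.DataFrame | None,
) -> tuple[np.ndarray, list[str]]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mats = pairwise_matrix(table, config, rcv_table=rcv_table)
    D = mats.distances
    if D.isna().any().any():
        keep = [t for t in D.index if not D.loc[t].drop(t).isna().all()]
        D = D.loc[keep, keep].fillna(D.stack().max())
    return ward_cluster(D), list(D.index)


def holdback_trial(
    table: pd.DataFrame,
    test_sizes: list[int],
    iterations: int = 10,
    config: AlgorithmConfig = AlgorithmConfig(),
    seed: int = 0,
    rcv_from: str = "train",
) -> HoldbackReport:
    """Run the holdback validation across test-set sizes.

    Per iteration: ``test_size`` animals are drawn at random as the test
    set, the threshold is tuned on the remaining (training) animals, and
    the test trails are clustered and counted.  ``rcv_from`` selects where
    the reference-centroid rows come from ("train" avoids leakage; "test"
    mirrors the alternative reading).
    """
    if rcv_from not in ("train", "test"):
        raise ValueError("rcv_from must be 'train' or 'test'")
    animals = sorted(table["animal_id"].dropna().unique())
    n_animals = len(animals)
    rng = np.random.default_rng(seed)
    results: list[HoldbackIteration] = []

    for size in test_sizes:
        if size >= n_animals:
            raise ValueError(f"test size {size} must be < library size {n_animals}")
        if n_animals - size < 2:
            raise ValueError(f"test size {size} leaves < 2 training animals")
        for it in range(iterations):
            test_animals = sorted(rng.choice(animals, size=size, replace=False))
            is_test = table["animal_id"].isin(test_animals)
            train_tab = table[~is_test]
            test_tab = table[is_test]

            # tune the threshold on the training animals only
            Z_train, train_trails = _cluster_trails(train_tab, config, None)
            truth_train = _truth_for(train_tab, train_trails)
            threshold = (
                tune_threshold(Z_train, truth_train, train_trails)
                if config.ward_threshold == "auto"
                else float(config.ward_threshold)
            )

            rcv_tab = train_tab if rcv_from == "train" else None
            Z_test, test_trails = _cluster_trails(test_tab, config, rcv_tab)
            predicted, _ = estimate_individuals(Z_test, threshold, test_trails)
            true_count = len(set(_truth_for(test_tab, test_trails)))
            accuracy = 100.0 - 100.0 * abs(predicted - true_count) / true_count
            results.append(
                HoldbackIteration(
                    test_size=size,
                    iteration=it,
                    test_animals=[str(a) for a in test_animals],
                    true_count=true_count,
                    predicted_count=predicted,
                    threshold=float(threshold),
                    accuracy=float(accuracy),
                )
            )
    return HoldbackReport(iterations=results, config=config, seed=seed)


def summarize_holdback(report: HoldbackReport) -> pd.DataFrame:
    """Tidy per-iteration table with the per-size mean prediction.

    Columns: size, expected, predicted, mean_predicted — one row per
    iteration, matching the validation plot's three series.
    """
    if not report.iterations:
        raise ValueError("empty holdback report")
    rows = [
        {
            "size": it.test_size,
            "expected": it.true_count,
            "predicted": it.predicted_count,
        }
        for it in report.iterations
    ]
    df = pd.DataFrame(rows)
    df["mean_predicted"] = df.groupby("size")["predicted"].transform("mean")
    return df[["size", "expected", "predicted", "mean_predicted"]]
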