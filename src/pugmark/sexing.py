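"""Sex classification of footprints by stepwise-selected linear discriminant.

Variables enter by forward stepwise partial F over the two sexes (the same
engine as the pairwise pipeline), then a two-class LDA with pooled
covariance and equal priors supplies the discriminant.  Validation is
leave-one-footprint-out jackknife (variable selection fixed from the full
data by default; ``strict`` re-selects per fold) and train/test partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .morphometry import DEFAULT_CATALOG
from .pairwise import stepwise_select, variable_columns

__all__ = [
    "SexModel",
    "fit_sex_model",
    "jackknife_accuracy",
    "accuracy_curve",
    "predict_sex",
    "TABLE1_SEX_PRESET",
]

# the 20 catalog variables flagged for sex discrimination
TABLE1_SEX_PRESET: list[str] = DEFAULT_CATALOG.sex_preset

_CLASSES = ("F", "M")


@dataclass
class SexModel:
    """A fitted two-class linear discriminant for sex."""

    variables: list[str]
    weights: np.ndarray     # discriminant vector w
    offset: float           # b; score = w'x + b, > 0 => male
    class_means: dict[str, np.ndarray]
    pooled_cov: np.ndarray
    n_per_sex: dict[str, int]
    f_ratios: list[float] | None = None

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.weights + self.offset

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "weights": [float(w) for w in self.weights],
            "offset": float(self.offset),
            "class_means": {k: [float(x) for x in v] for k, v in self.class_means.items()},
            "pooled_cov": [[float(x) for x in row] for row in self.pooled_cov],
            "n_per_sex": {k: int(v) for k, v in self.n_per_sex.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SexModel":
        return cls(
            variables=list(d["variables"]),
            weights=np.asarray(d["weights"], float),
            offset=float(d["offset"]),
            class_means={k: np.asarray(v, float) for k, v in d["class_means"].items()},
            pooled_cov=np.asarray(d["pooled_cov"], float),
            n_per_sex={k: int(v) for k, v in d["n_per_sex"].items()},
        )


def _split_xy(table: pd.DataFrame, variables: list[str]) -> tuple[np.ndarray, np.ndarray]:
    sex = table["sex"].astype(str).to_numpy()
    known = np.isin(sex, _CLASSES)
    if not np.all(known):
        table = table[known]
        sex = sex[known]
    X = table[variables].to_numpy(float)
    return X, sex


def _lda_from_arrays(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, dict, np.ndarray]:
    """Closed-form pooled-covariance two-class LDA with equal priors."""
    means = {}
    resid = []
    for cls in _CLASSES:
        rows = X[y == cls]
        if len(rows) < 2:
            raise ValueError(f"need >= 2 footprints of sex {cls!r}")
        means[cls] = rows.mean(axis=0)
        resid.append(rows - means[cls])
    R = np.vstack(resid)
    n = X.shape[0]
    Sp = (R.T @ R) / (n - 2)
    # mild ridge only if singular
    try:
        w = np.linalg.solve(Sp, means["M"] - means["F"])
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(Sp) / Sp.shape[0]
        w = np.linalg.solve(Sp + eps * np.eye(Sp.shape[0]), means["M"] - means["F"])
    b = -float(w @ (means["M"] + means["F"])) / 2.0
    return w, b, means, Sp


def fit_sex_model(
    table: pd.DataFrame,
    n_vars: int = 20,
    preset: list[str] | None = None,
) -> SexModel:
    """Fit the stepwise-selected sex discriminant.

    ``preset`` bypasses selection with a fixed variable list (e.g.
    ``TABLE1_SEX_PRESET``, the 20 flagged catalog variables).
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    vcols = variable_columns(table)
    X, y = _split_xy(table, vcols)
    present = set(np.unique(y))
    if not set(_CLASSES) <= present:
        raise ValueError(f"both sexes must be present in training data; got {present}")

    f_ratios: list[float] | None = None
    if preset is not None:
        missing = [v for v in preset if v not in vcols]
        if missing:
            raise ValueError(f"preset variables missing from table: {missing}")
        variables = list(preset)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected = stepwise_select(X, y, n_vars, names=vcols)
        if not selected:
            raise ValueError("stepwise selection found no informative variables")
        variables = [v for v, _ in selected]
        f_ratios = [f for _, f in selected]

    idx = [vcols.index(v) for v in variables]
    w, b, means, Sp = _lda_from_arrays(X[:, idx], y)
    return SexModel(
        variables=variables,
        weights=w,
        offset=b,
        class_means=means,
        pooled_cov=Sp,
        n_per_sex={cls: int((y == cls).sum()) for cls in _CLASSES},
        f_ratios=f_ratios,
    )


def jackknife_accuracy(
    table: pd.DataFrame,
    n_vars: int = 20,
    preset: list[str] | None = None,
    strict: bool = False,
) -> float:
    """Leave-one-footprint-out percent correct of the sex discriminant.

    By default the variable selection is fixed from the full data and only
    the LDA weights are refit per fold; ``strict=True`` re-runs the
    selection inside every fold.
    """
    vcols = variable_columns(table)
    X, y = _split_xy(table, vcols)
    n = len(y)
    if n < 3:
        raise ValueError("too few labelled footprints for jackknife")

    if not strict:
        model = fit_sex_model(table, n_vars=n_vars, preset=preset)
        idx = [vcols.index(v) for v in model.variables]

    correct = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        if strict:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = stepwise_select(Xi, yi, n_vars, names=vcols)
            fold_idx = [vcols.index(v) for v, _ in sel]
        else:
            fold_idx = idx
        w, b, _, _ = _lda_from_arrays(Xi[:, fold_idx], yi)
        pred = "M" if X[i, fold_idx] @ w + b > 0 else "F"
        correct += pred == y[i]
        mask[i] = True
    return 100.0 * correct / n


def accuracy_curve(
    table: pd.DataFrame, var_counts: list[int]
) -> list[tuple[int, float]]:
    """Jackknife accuracy as a function of the number of selected variables.

    Selections are nested: the stepwise ordering is computed once at the
    largest requested count and truncated, so consecutive points differ only
    by the added variable.
    """
    if not var_counts:
        raise ValueError("var_counts must be non-empty")
    vcols = variable_columns(table)
    X, y = _split_xy(table, vcols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selected = stepwise_select(X, y, max(var_counts), names=vcols)
    order = [v for v, _ in selected]
    curve = []
    for k in var_counts:
        preset = order[: min(k, len(order))]
        curve.append((k, jackknife_accuracy(table, preset=preset)))
    return curve


def predict_sex(model: SexModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-footprint sex labels and posteriors, plus a trail majority label.

    The posterior is the exact equal-priors Gaussian posterior, which for
    pooled-covariance LDA is logistic in the discriminant score.  Trail
    ties resolve toward the label with the higher mean posterior.
    """
    missing = [v for v in model.variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing model variables in table: {missing}")
    X = table[model.variables].to_numpy(float)
    if not np.all(np.isfinite(X)):
        bad = [model.variables[j] for j in np.unique(np.argwhere(~np.isfinite(X))[:, 1])]
        raise ValueError(f"non-finite values in model variables: {bad}")
    scores = model.decision_scores(X)
    post_m = expit(scores)
    labels = np.where(scores > 0, "M", "F")
    out = pd.DataFrame(
        {
            "footprint_id": table["footprint_id"].to_numpy(),
            "trail_id": table["trail_id"].to_numpy(),
            "predicted_sex": labels,
            "posterior_male": post_m,
        }
    )
    trail_labels = {}
    for tid, sub in out.groupby("trail_id"):
        n_m = int((sub["predicted_sex"] == "M").sum())
        n_f = len(sub) - n_m
        if n_m > n_f:
            lab = "M"
        elif n_f > n_m:
            lab = "F"
        else:
            lab = "M" if sub["posterior_male"].mean() >= 0.5 else "F"
        trail_labels[tid] = lab
    out["trail_predicted_sex"] = out["trail_id"].map(trail_labels)
    return out
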