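"""Cross-validated predictive scoring of site/indicator models.

Each model's data are split into k (default ten) random folds; each fold is
withheld while a LARS-lasso/minimum-Cp sub-model is trained on the rest —
including re-standardization of the training covariates, so no information
leaks from the withheld fold — yielding exactly one prediction per
observation.  Predictions feed two metrics:

* SRMSEP = sqrt(mean((P_i - O_i)^2)) / C_bar, the root mean squared error
  of prediction standardized by the mean log10 concentration of the
  modeled indicator (lower is better);
* R2_pred, the coefficient of determination of the simple regression of
  predictions on observations (higher is better).

To compare models across sites and indicators each metric is divided by its
maximum over the compared model set and combined into
Overall Performance = standardized R2_pred + (1 - standardized SRMSEP),
which lives in [0, 2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from beachcast.lars import SelectedModel, lars_fit, select_min_cp
from beachcast.preprocess import ModelFrame, apply_standardization, standardize

__all__ = [
    "CVPredictions",
    "kfold_predict",
    "srmsep",
    "r2_pred",
    "overall_performance",
    "build_board",
    "score_frame",
]


@dataclass
class CVPredictions:
    table: pd.DataFrame  # columns: index, fold, observed, predicted
    k: int
    seed: int

    @property
    def observed(self) -> np.ndarray:
        return self.table["observed"].to_numpy()

    @property
    def predicted(self) -> np.ndarray:
        return self.table["predicted"].to_numpy()


def kfold_predict(frame: ModelFrame, k: int = 10, seed: int = 0) -> CVPredictions:
    """One out-of-fold prediction per observation from k sub-models.

    Folds are a random permutation cut into k nearly equal blocks (sizes
    differ by at most one).  Training covariates are re-standardized per
    fold; columns that are constant within a training fold are dropped from
    that sub-model with a warning.
    """
    n = len(frame.y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"n={n} observations cannot be split into k={k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    raw = frame.raw_X().reset_index(drop=True)
    y = np.asarray(frame.y, dtype=float)

    rows = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        X_train = raw.iloc[train_idx]
        usable = X_train.columns[X_train.std(ddof=1) > 0]
        if len(usable) < raw.shape[1]:
            warnings.warn(
                f"fold {fold_id}: dropping constant training column(s) "
                f"{sorted(set(raw.columns) - set(usable))}"
            )
        Z_train, params = standardize(X_train[usable])
        path = lars_fit(Z_train, y[train_idx])
        model = select_min_cp(path)
        Z_test = apply_standardization(raw.iloc[test_idx][usable], params)
        pred = model.predict(Z_test)
        for i, p in zip(test_idx, pred):
            rows.append({"index": int(i), "fold": fold_id, "observed": y[i], "predicted": p})
    table = pd.DataFrame(rows).sort_values("index").reset_index(drop=True)
    return CVPredictions(table=table, k=k, seed=seed)


def srmsep(predictions: np.ndarray, observations: np.ndarray, mean_log10_concentration: float) -> float:
    """Root mean squared prediction error / mean log10 concentration."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predictions and observations must have equal length")
    if mean_log10_concentration == 0:
        raise ValueError("mean log10 concentration of 0 leaves SRMSEP undefined")
    return float(np.sqrt(np.mean((p - o) ** 2)) / mean_log10_concentration)


def r2_pred(predictions: np.ndarray, observations: np.ndarray) -> float:
    """R2 of the simple regression of predictions on observations.

    Equals the squared Pearson correlation.  Zero-variance predictions (a
    constant sub-model everywhere) carry no predictive association: returns
    0 with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if np.var(o) == 0:
        raise ValueError("observations have zero variance")
    if np.var(p) == 0:
        warnings.warn("zero-variance predictions; R2_pred set to 0")
        return 0.0
    r = np.corrcoef(p, o)[0, 1]
    return float(r * r)


def overall_performance(std_rpred2: float, std_srmsep: float) -> float:
    """Composite score: standardized R2_pred + (1 - standardized SRMSEP)."""
    return float(std_rpred2 + (1.0 - std_srmsep))


def score_frame(frame: ModelFrame, k: int = 10, seed: int = 0) -> dict:
    """CV-score one model: returns rpred2, srmsep, c_bar and the predictions.

    C_bar is the mean of the full observed (substituted) log10 response of
    the model's dataset, not of the withheld folds.
    """
    cv = kfold_predict(frame, k=k, seed=seed)
    c_bar = float(np.mean(frame.y))
    return {
        "site": frame.site,
        "indicator": frame.indicator,
        "rpred2": r2_pred(cv.predicted, cv.observed),
        "srmsep": srmsep(cv.predicted, cv.observed, c_bar),
        "c_bar": c_bar,
        "cv": cv,
    }


def build_board(metrics: pd.DataFrame) -> pd.DataFrame:
    """Cross-model standardization and Overall Performance.

    ``metrics`` needs columns site, indicator, rpred2, srmsep (one row per
    model).  Each metric is divided by its maximum over the supplied model
    set, so standardized values depend on — and are only reproducible with —
    an explicit model set.
    """
    required = {"site", "indicator", "rpred2", "srmsep"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    if len(metrics) == 0:
        raise ValueError("empty model set")
    board = metrics.copy().reset_index(drop=True)
    max_r2 = board["rpred2"].max()
    max_sr = board["srmsep"].max()
    if max_r2 <= 0 or max_sr <= 0:
        raise ValueError("standardization requires a positive maximum for each metric")
    board["std_rpred2"] = board["rpred2"] / max_r2
    board["std_srmsep"] = board["srmsep"] / max_sr
    board["overall_performance"] = [
        overall_performance(a, b) for a, b in zip(board["std_rpred2"], board["std_srmsep"])
    ]
    cols = ["site", "indicator", "rpred2", "srmsep", "std_rpred2", "std_srmsep",
            "overall_performance"]
    extra = [c for c in board.columns if c not in cols]
    return board[cols + extra]
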