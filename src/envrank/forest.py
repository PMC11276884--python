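"""Random-forest regression with grid-search/CV tuning and error metrics.

The prediction function f-hat used by all importance measures is a random
forest: the regression output is the average of the individual trees.  The
two hyperparameters that matter are the number of trees (``n_trees``) and
the number of candidate features per split (``mtry``); they are tuned by
exhaustive grid search with k-fold cross-validation on the training set,
minimising mean squared validation error.

Performance is summarised by the triple

    MAE  = mean |y_i - yhat_i|
    MARE = mean |y_i - yhat_i| / y_i      (over rows with y_i != 0 by default)
    R^2  = 1 - SS_res / SS_tot

MARE is undefined at zero counts; daily admission series do contain zero
days, so the zero policy (exclude, or add an epsilon) is an explicit
argument and is recorded with the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .tables import FeatureTable

__all__ = [
    "TunedForest",
    "PerformanceTriple",
    "split_train_test",
    "default_grid",
    "tune_forest",
    "predict",
    "performance_indices",
]


def split_train_test(
    table: FeatureTable,
    train_fraction: float = 0.8,
    mode: str = "random",
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Partition rows into disjoint, exhaustive train/test sets.

    ``random`` shuffles rows with the given seed; ``chronological`` places
    the latest dates in the test set.  The train size is
    ``floor(train_fraction * n)``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = table.n
    if n < 5:
        raise ValueError(f"need at least 5 rows to split, got {n}")
    n_train = int(math.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"degenerate split: {n_train} train rows out of {n}"
        )
    if mode == "random":
        order = np.random.default_rng(seed).permutation(n)
        train_idx = np.sort(order[:n_train])
        test_idx = np.sort(order[n_train:])
    elif mode == "chronological":
        order = np.argsort(table.dates.values, kind="stable")
        train_idx = order[:n_train]
        test_idx = order[n_train:]
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return table.take(train_idx), table.take(test_idx)


@dataclass
class TunedForest:
    """Fitted forest plus the tuning record that produced it."""

    estimator: RandomForestRegressor
    feature_names: list[str]
    target: str
    hyperparameters: dict
    cv_record: list[dict]
    seed: int

    def predict(self, X) -> np.ndarray:
        return predict(self, X)

    def summary(self) -> dict:
        return {
            "target": self.target,
            "feature_names": self.feature_names,
            "hyperparameters": self.hyperparameters,
            "cv_record": self.cv_record,
            "seed": self.seed,
        }


def default_grid(d: int) -> list[tuple[int, int]]:
    """Default search grid: n_trees in {100, 300, 500}, mtry in
    {ceil(d/3), ceil(sqrt(d)), d} (deduplicated)."""
    mtrys = sorted({max(1, math.ceil(d / 3)), max(1, math.ceil(math.sqrt(d))), d})
    return [(t, m) for t in (100, 300, 500) for m in mtrys]


def tune_forest(
    train: FeatureTable,
    grid: list[tuple[int, int]] | None = None,
    k: int = 5,
    seed: int = 0,
    target: str | None = None,
) -> TunedForest:
    """Grid search over (n_trees, mtry) with k-fold CV, then refit on all rows.

    Every grid point is scored by mean squared validation error averaged
    over the k folds (each row validated exactly once).  The winner is the
    argmin; exact ties go to the smaller ``n_trees``, then smaller ``mtry``.
    """
    if grid is None:
        grid = default_grid(train.d)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > train.n:
        raise ValueError(f"k={k} exceeds number of training rows {train.n}")
    target = target or train.target_names[0]
    X = train.features.to_numpy(dtype=float)
    y = train.targets[target].to_numpy(dtype=float)
    d = X.shape[1]
    for n_trees, mtry in grid:
        if not 1 <= mtry <= d:
            raise ValueError(f"mtry={mtry} outside [1, {d}]")
        if n_trees < 1:
            raise ValueError(f"n_trees={n_trees} must be positive")

    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))
    record = []
    for n_trees, mtry in grid:
        fold_mse = []
        for tr_idx, va_idx in folds:
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
            )
            rf.fit(X[tr_idx], y[tr_idx])
            resid = y[va_idx] - rf.predict(X[va_idx])
            fold_mse.append(float(np.mean(resid**2)))
        record.append(
            {"n_trees": n_trees, "mtry": mtry, "cv_mse": float(np.mean(fold_mse))}
        )

    winner = min(record, key=lambda r: (r["cv_mse"], r["n_trees"], r["mtry"]))
    rf = RandomForestRegressor(
        n_estimators=winner["n_trees"],
        max_features=winner["mtry"],
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return TunedForest(
        estimator=rf,
        feature_names=train.feature_names,
        target=target,
        hyperparameters={"n_trees": winner["n_trees"], "mtry": winner["mtry"]},
        cv_record=record,
        seed=seed,
    )


def predict(forest: TunedForest, X) -> np.ndarray:
    """Forest prediction (average of per-tree predictions) for m rows."""
    if isinstance(X, pd.DataFrame):
        if set(X.columns) != set(forest.feature_names):
            raise ValueError(
                f"column mismatch: model expects {forest.feature_names}, "
                f"got {list(X.columns)}"
            )
        X = X[forest.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(forest.feature_names):
            raise ValueError(
                f"expected m x {len(forest.feature_names)} matrix, got shape "
                f"{X.shape}"
            )
    if X.shape[0] == 0:
        return np.empty(0)
    return forest.estimator.predict(X)


@dataclass
class PerformanceTriple:
    """MAE / MARE / R-squared on one evaluation set."""

    mae: float
    mare: float
    r2: float
    zero_policy: str = field(default="exclude", compare=False)
    n_mare: int = field(default=0, compare=False)  # rows entering the MARE mean

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mae, self.mare, self.r2)

    def to_dict(self) -> dict:
        return {"mae": self.mae, "mare": self.mare, "r2": self.r2}


def performance_indices(
    y: np.ndarray,
    yhat: np.ndarray,
    zero_policy: str = "exclude",
    epsilon: float = 0.5,
) -> PerformanceTriple:
    """Compute the (MAE, MARE, R^2) triple.

    ``zero_policy`` controls rows with ``y_i == 0`` in the MARE sum:
    ``exclude`` drops them (the mean runs over the remaining rows);
    ``epsilon`` divides by ``y_i + epsilon`` for those rows instead.
    R^2 may be negative for fits worse than the mean predictor.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be equal-length vectors")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    if zero_policy not in ("exclude", "epsilon"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    abs_err = np.abs(y - yhat)
    mae = float(np.mean(abs_err))

    nonzero = y != 0
    if zero_policy == "exclude":
        if not np.any(nonzero):
            raise ValueError("all observed values are zero; MARE undefined")
        mare = float(np.mean(abs_err[nonzero] / y[nonzero]))
        n_mare = int(np.count_nonzero(nonzero))
    else:
        denom = np.where(nonzero, y, y + epsilon)
        mare = float(np.mean(abs_err / denom))
        n_mare = len(y)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed vector has zero variance; R^2 undefined")
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return PerformanceTriple(mae, mare, r2, zero_policy=zero_policy, n_mare=n_mare)
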