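"""Per-participant gradient-boosted-tree modeling.

Each person gets their own binary XGBoost classifier per feature schema,
selected by a grid search scored with 4-fold rolling-origin (expanding
window) cross-validation on the chronological first 70% of their
observations, and evaluated once on the held-out final 30%.

The default hyperparameter grid follows the analysis protocol this package
replicates; two of its printed values are outside XGBoost's legal domain
(a negative gamma and a column-subsample ratio above 1) and are sanitized
before fitting (see :func:`HyperGrid.sanitized_points`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import PersonMatrix

#: classification threshold on the predicted excursion probability
THRESHOLD = 0.5


@dataclass
class HyperGrid:
    """Grid-search space for the per-person boosters."""

    n_rounds: tuple[int, ...] = (50, 100, 150)
    eta: tuple[float, ...] = (0.0, 0.0001, 0.001, 0.01, 0.015)
    max_depth: tuple[int, ...] = (1, 2, 3)
    gamma: tuple[float, ...] = (-0.5, 0.0, 0.5)
    colsample_bytree: tuple[float, ...] = (0.5, 1.0, 2.0)
    min_child_weight: tuple[float, ...] = (1.0, 2.0)
    subsample: tuple[float, ...] = (1.0,)

    def sanitized_points(self) -> list[dict[str, float]]:
        """Legal, de-duplicated grid points.

        gamma must be ≥ 0 (−0.5 → 0) and colsample_bytree a fraction in
        (0, 1] (2 → 1); the resulting duplicates collapse.  eta = 0 is legal
        (it yields a constant booster) and is retained.
        """
        gammas = sorted({max(g, 0.0) for g in self.gamma})
        colsamples = sorted({min(c, 1.0) for c in self.colsample_bytree})
        pts = []
        for nr, eta, md, g, cs, mcw, sub in itertools.product(
            self.n_rounds, self.eta, self.max_depth, gammas, colsamples, self.min_child_weight, self.subsample
        ):
            pts.append(
                {
                    "n_rounds": nr,
                    "eta": eta,
                    "max_depth": md,
                    "gamma": g,
                    "colsample_bytree": cs,
                    "min_child_weight": mcw,
                    "subsample": sub,
                }
            )
        return pts


#: reduced grid for quick runs and tests: the corners of the sanitized grid
#: that can actually learn (largest eta, extreme depths, both round counts)
FAST_GRID = HyperGrid(
    n_rounds=(50, 150),
    eta=(0.015,),
    max_depth=(1, 3),
    gamma=(0.0,),
    colsample_bytree=(1.0,),
    min_child_weight=(1.0,),
)


@dataclass
class FitResult:
    """Outcome of one participant × schema grid search + final fit."""

    participant_id: str
    schema: str
    chosen_params: dict[str, float]
    cv_scores: list[float | None]  # per-fold F1 of the chosen point
    booster: xgb.Booster | None
    feature_names: list[str]
    train_idx: np.ndarray
    test_idx: np.ndarray
    fallback_majority: int | None = None  # set when no grid point scored
    seed: int = 0

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if self.booster is None:
            return np.full(len(X), 1.0 if self.fallback_majority == 1 else 0.0)
        d = xgb.DMatrix(X[self.feature_names], feature_names=self.feature_names)
        return self.booster.predict(d)

    def predict(self, X: pd.DataFrame, threshold: float = THRESHOLD) -> np.ndarray:
        return (self.predict_proba(X) > threshold).astype(int)


def chrono_split(n: int, train_frac: float = 0.70) -> tuple[np.ndarray, np.ndarray]:
    """First floor(train_frac·n) rows train, remainder test; no shuffling.

    Requires n ≥ 20 so the split yields at least 14 training and 6 test
    rows — participants below that are filtered upstream.
    """
    if n < 20:
        raise ValueError("chronological split requires at least 20 observations")
    n_train = int(np.floor(train_frac * n))
    return np.arange(n_train), np.arange(n_train, n)


def rolling_origin_folds(n_train: int, k: int = 4) -> list[tuple[np.ndarray, np.ndarray]]:
    """Expanding-window CV folds over a chronological training block.

    The training rows are cut into k+1 contiguous near-equal blocks (earlier
    blocks absorb the remainder); fold j fits on blocks 1..j and validates
    on block j+1, so every validation index is strictly later than every fit
    index of its fold.
    """
    if n_train < k + 1:
        raise ValueError(f"rolling-origin CV needs at least {k + 1} rows, got {n_train}")
    base, rem = divmod(n_train, k + 1)
    sizes = [base + 1 if i < rem else base for i in range(k + 1)]
    bounds = np.cumsum([0] + sizes)
    folds = []
    for j in range(1, k + 1):
        fit_idx = np.arange(0, bounds[j])
        val_idx = np.arange(bounds[j], bounds[j + 1])
        folds.append((fit_idx, val_idx))
    return folds


def _f1_positive(y_true: np.ndarray, y_pred: np.ndarray) -> float | None:
    """F1 of the positive class; None when precision or recall is undefined."""
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    if tp + fp == 0 or tp + fn == 0:
        return None
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _xgb_params(point: dict[str, float], seed: int) -> dict:
    return {
        "objective": "binary:logistic",
        "eta": point["eta"],
        "max_depth": int(point["max_depth"]),
        "gamma": point["gamma"],
        "colsample_bytree": point["colsample_bytree"],
        "min_child_weight": point["min_child_weight"],
        "subsample": point["subsample"],
        "tree_method": "exact",
        "nthread": 1,
        "seed": seed,
        "base_score": 0.5,
    }


def _fit_booster(X: pd.DataFrame, y: np.ndarray, point: dict[str, float], seed: int) -> xgb.Booster:
    d = xgb.DMatrix(X, label=y, feature_names=list(X.columns))
    return xgb.train(_xgb_params(point, seed), d, num_boost_round=int(point["n_rounds"]), verbose_eval=False)


def grid_search_fit(
    matrix: PersonMatrix,
    grid: HyperGrid | None = None,
    seed: int = 0,
    k: int = 4,
    threshold: float = THRESHOLD,
) -> FitResult:
    """Rolling-origin CV grid search on the training rows, then a final fit.

    Each sanitized grid point is scored by the mean F1 (positive class,
    fixed 0.5 threshold) over the folds where F1 is defined; folds whose
    validation block draws no positive predictions or contains no positive
    labels score undefined and drop out of the mean.  Ties prefer the
    simplest model: fewer rounds, then shallower trees, then larger eta.
    If every fold of every point is undefined the participant falls back to
    a majority-class predictor, flagged on the result.
    """
    grid = grid if grid is not None else HyperGrid()
    X, y = matrix.X, matrix.y
    train_idx = matrix.train_idx
    Xtr = X.iloc[train_idx]
    ytr = y[train_idx]
    folds = rolling_origin_folds(len(train_idx), k=k)

    best: tuple | None = None  # (-mean_f1, n_rounds, max_depth, -eta, order) for min()
    best_point: dict[str, float] | None = None
    best_scores: list[float | None] | None = None
    for order, point in enumerate(grid.sanitized_points()):
        scores: list[float | None] = []
        for fit_idx, val_idx in folds:
            booster = _fit_booster(Xtr.iloc[fit_idx], ytr[fit_idx], point, seed)
            dval = xgb.DMatrix(Xtr.iloc[val_idx], feature_names=list(X.columns))
            pred = (booster.predict(dval) > threshold).astype(int)
            scores.append(_f1_positive(ytr[val_idx], pred))
        defined = [s for s in scores if s is not None]
        if not defined:
            continue
        mean_f1 = float(np.mean(defined))
        key = (-mean_f1, point["n_rounds"], point["max_depth"], -point["eta"], order)
        if best is None or key < best:
            best = key
            best_point = point
            best_scores = scores

    if best_point is None:
        majority = int(np.round(ytr.mean()))  # ties favor the positive class
        return FitResult(
            matrix.participant_id,
            matrix.schema,
            {},
            [],
            None,
            matrix.feature_names,
            train_idx,
            matrix.test_idx,
            fallback_majority=majority,
            seed=seed,
        )

    booster = _fit_booster(Xtr, ytr, best_point, seed)
    return FitResult(
        matrix.participant_id,
        matrix.schema,
        best_point,
        best_scores or [],
        booster,
        matrix.feature_names,
        train_idx,
        matrix.test_idx,
        seed=seed,
    )
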