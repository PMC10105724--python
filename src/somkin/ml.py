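"""Prediction of decomposition kinetics parameters from edaphic-climatic covariates.

Eight kinetics parameters (M2-k1, M2-k2, M2-f1, M3-k1, M3-k2, M3-k3, M3-f1,
M3-f2) are regressed on eleven covariates (MAP, MAT, Sand, Clay, pH, SOC, MBC,
Elev, Slope, NDVI, IncT) with multiple linear regression (MLR), gradient
boosting (GBM) or random forest (RF).  The workflow mirrors the standard
protocol for this kind of synthesis:

* 75/25 quantile-stratified train/test partition,
* recursive feature elimination (RFE) scored by 10-fold CV R²,
* hyperparameter grid search under repeated 10-fold CV (3 repeats),
* repeated restarts with selection of the best validation R²,
* final model choice by the SSE-based AIC (see :mod:`somkin.metrics`),
* permutation variable importance normalized to sum to 100%,
* partial dependence on a 0-1 normalized covariate axis.

Rates span several orders of magnitude and are modeled as log10(k); pool
fractions are modeled raw.  Reported metrics are computed on the model scale.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import (GridSearchCV, KFold, RepeatedKFold,
                                     cross_val_score, train_test_split)

from . import metrics as _metrics

__all__ = [
    "COVARIATES", "TARGETS", "TARGET_TRANSFORMS", "KineticsParameterRegressor",
    "TrainedModel", "partition", "rfe_select", "train_model",
    "repeat_and_select", "compare_by_aic", "variable_importance",
    "partial_dependence",
]

COVARIATES = ["MAP", "MAT", "Sand", "Clay", "pH", "SOC", "MBC", "Elev",
              "Slope", "NDVI", "IncT"]

TARGETS = ["M2_k1", "M2_k2", "M2_f1", "M3_k1", "M3_k2", "M3_k3",
           "M3_f1", "M3_f2"]

#: rates are log10-transformed before regression; fractions are modeled raw
TARGET_TRANSFORMS = {t: ("log10" if "_k" in t else "identity") for t in TARGETS}

# GBM: n.trees 10-200, interaction.depth 1-7, shrinkage {0.01, 0.1},
# n.minobsinnode fixed at 10.  RF: <= 100 trees, mtry in 2..p-1.
DEFAULT_GBM_GRID = {
    "n_estimators": [10, 50, 100, 150, 200],
    "max_depth": [1, 2, 3, 4, 5, 6, 7],
    "learning_rate": [0.01, 0.1],
    "min_samples_leaf": [10],
}


def _as_frame(X):
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _base_estimator(method, seed=None, n_trees=100):
    if method == "mlr":
        return LinearRegression()
    if method == "gbm":
        return GradientBoostingRegressor(random_state=seed, min_samples_leaf=10)
    if method == "rf":
        return RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    raise ValueError(f"unknown method {method!r}; use 'mlr', 'gbm' or 'rf'")


def _importance_ranking(est, X, y):
    """Feature ranking for RFE: model importances, or |standardized coef| for MLR."""
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    coef = np.abs(np.asarray(est.coef_, dtype=float).ravel())
    return coef * X.std(axis=0).to_numpy()


class KineticsParameterRegressor(BaseEstimator, RegressorMixin):
    """One kinetics parameter regressed on covariates (MLR / GBM / RF).

    Parameters
    ----------
    method : {"rf", "gbm", "mlr"}
    rfe : bool
        Run recursive feature elimination before the final fit.
    target_transform : {"identity", "log10"}
        Applied to y before fitting and inverted on prediction.
    cv_folds, cv_repeats : int
        Repeated k-fold design for the hyperparameter grid search.
    grid : dict or None
        Hyperparameter grid; None uses the method default.
    n_trees : int
        RF forest size (the grid tunes ``max_features``/mtry only).
    rfe_tie_tol : float
        Subsets within this CV-R² of the best are ties; smallest wins.
    random_state : int or None
    """

    def __init__(self, method="rf", rfe=True, target_transform="identity",
                 cv_folds=10, cv_repeats=3, grid=None, n_trees=100,
                 rfe_tie_tol=0.01, random_state=None):
        self.method = method
        self.rfe = rfe
        self.target_transform = target_transform
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.grid = grid
        self.n_trees = n_trees
        self.rfe_tie_tol = rfe_tie_tol
        self.random_state = random_state

    # -- target scale --------------------------------------------------------

    def _ty(self, y):
        y = np.asarray(y, dtype=float)
        if self.target_transform == "log10":
            if np.any(y <= 0):
                raise ValueError("log10 transform requires positive targets")
            return np.log10(y)
        return y

    def _inv_ty(self, z):
        return 10.0 ** z if self.target_transform == "log10" else z

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y):
        X = _as_frame(X)
        z = self._ty(y)
        if not np.all(np.isfinite(X.to_numpy())):
            raise ValueError("X contains missing or non-finite entries")
        if np.ptp(z) == 0:
            raise ValueError("degenerate target: y is constant")
        self.feature_names_in_ = list(X.columns)
        self.n_features_in_ = X.shape[1]

        if self.rfe:
            self.selected_features_, self.rfe_profile_ = rfe_select(
                X, z, method=self.method, folds=min(self.cv_folds, len(z)),
                seed=self.random_state, tie_tol=self.rfe_tie_tol,
                n_trees=self.n_trees)
        else:
            self.selected_features_ = list(X.columns)
            self.rfe_profile_ = None
        Xs = X[self.selected_features_]

        grid = self.grid
        if grid is None:
            if self.method == "gbm":
                grid = DEFAULT_GBM_GRID
            elif self.method == "rf":
                p = len(self.selected_features_)
                mtry = list(range(2, p)) or [1]
                grid = {"max_features": mtry}
            else:
                grid = {}
        base = _base_estimator(self.method, seed=self.random_state,
                               n_trees=self.n_trees)
        if grid:
            cv = RepeatedKFold(n_splits=min(self.cv_folds, len(z)),
                               n_repeats=self.cv_repeats,
                               random_state=self.random_state)
            gs = GridSearchCV(base, grid, scoring="r2", cv=cv, n_jobs=None,
                              error_score="raise")
            gs.fit(Xs, z)
            if not np.isfinite(gs.best_score_):
                raise RuntimeError("grid exhausted without a finite CV score")
            self.estimator_ = gs.best_estimator_
            self.best_params_ = gs.best_params_
            self.cv_r2_ = float(gs.best_score_)
        else:
            self.estimator_ = clone(base).fit(Xs, z)
            self.best_params_ = {}
            cv = KFold(n_splits=min(self.cv_folds, len(z)), shuffle=True,
                       random_state=self.random_state)
            self.cv_r2_ = float(np.mean(cross_val_score(
                clone(base), Xs, z, scoring="r2", cv=cv)))
            self.estimator_.fit(Xs, z)
        return self

    def _select(self, X):
        X = _as_frame(X)
        if set(self.selected_features_) <= set(X.columns):
            return X[self.selected_features_]
        # positional fallback for bare arrays matching the training layout
        idx = [self.feature_names_in_.index(f) for f in self.selected_features_]
        return X.iloc[:, idx].set_axis(self.selected_features_, axis=1)

    def predict(self, X):
        return self._inv_ty(self.estimator_.predict(self._select(X)))

    def predict_per_tree(self, X):
        """Per-tree predictions (n_trees, n_samples), original target scale."""
        if not isinstance(self.estimator_, RandomForestRegressor):
            raise TypeError("per-tree predictions require an RF model")
        Xs = self._select(X).to_numpy()
        preds = np.stack([t.predict(Xs) for t in self.estimator_.estimators_])
        return self._inv_ty(preds)

    # -- interpretation ------------------------------------------------------

    def feature_importance(self, X, y, n_repeats=10, random_state=None):
        """Relative variable importance, non-negative and summing to 100 (%).

        RF/GBM use permutation importance of the model-scale R² on the given
        data; MLR uses absolute standardized coefficients.  Features dropped
        by RFE score 0.
        """
        X = _as_frame(X)
        Xs = self._select(X)
        imp = pd.Series(0.0, index=self.feature_names_in_)
        if self.method == "mlr":
            raw = np.abs(self.estimator_.coef_.ravel()) * \
                Xs.std(axis=0).to_numpy()
        else:
            z = self._ty(y)
            res = permutation_importance(
                self.estimator_, Xs, z, scoring="r2",
                n_repeats=n_repeats,
                random_state=self.random_state if random_state is None
                else random_state)
            raw = np.clip(res.importances_mean, 0.0, None)
        if raw.sum() == 0:
            raw = np.ones_like(raw)
        imp[self.selected_features_] = 100.0 * raw / raw.sum()
        return imp


@dataclass
class TrainedModel:
    """A fitted predictor with its evaluation context."""

    method: str
    target_name: str
    regressor: KineticsParameterRegressor
    selected_features: list
    best_params: dict
    cv_r2: float
    train_metrics: dict
    test_metrics: dict
    aic: float
    seed: int | None
    n_eval: int
    eval_checksum: str
    X_test: pd.DataFrame | None = None
    y_test: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def predict(self, X):
        return self.regressor.predict(X)

    def predict_per_tree(self, X):
        return self.regressor.predict_per_tree(X)

    @property
    def selected_features_(self):
        return self.regressor.selected_features_

    @property
    def target_name_(self):
        return self.target_name


# ---------------------------------------------------------------------------
# workflow functions
# ---------------------------------------------------------------------------

def partition(X, y, train_fraction=0.75, seed=None, n_bins=5):
    """Quantile-stratified train/test split.

    ``y`` is binned into ``n_bins`` quantile classes and the split is
    stratified on them; with too few rows for stratification a simple random
    split is used (with a warning).  Returns (X_train, X_test, y_train,
    y_test, idx_train, idx_test).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    X = _as_frame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    idx = np.arange(len(y))
    strat = None
    if len(y) >= 4 * n_bins:
        bins = pd.qcut(y, q=n_bins, labels=False, duplicates="drop")
        if pd.Series(bins).value_counts().min() >= 2:
            strat = bins
    if strat is None:
        warnings.warn("too few rows for quantile stratification; "
                      "falling back to simple random split")
    tr, te = train_test_split(idx, train_size=train_fraction,
                              random_state=seed, stratify=strat)
    tr.sort(), te.sort()
    return X.iloc[tr], X.iloc[te], y[tr], y[te], tr, te


def rfe_select(X, y, method="rf", folds=10, seed=None, tie_tol=0.01,
               n_trees=100):
    """Backward recursive feature elimination scored by k-fold CV R².

    From all features down to one, the least-important feature (model
    importance, or |standardized coefficient| for MLR) is dropped at each
    step and the subset's CV R² recorded.  The subset maximizing CV R² wins;
    subsets within ``tie_tol`` of the best count as ties and the smallest is
    returned (under a pure-noise target no subset clears the threshold and
    the single-feature subset is returned).

    Returns (selected_features, profile) where profile is a DataFrame with
    one row per subset size.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: y is constant")
    current = list(X.columns)
    cv = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
    rows = []
    while current:
        est = _base_estimator(method, seed=seed, n_trees=n_trees)
        score = float(np.mean(cross_val_score(est, X[current], y,
                                              scoring="r2", cv=cv)))
        rows.append({"size": len(current), "cv_r2": score,
                     "features": tuple(current)})
        if len(current) == 1:
            break
        est.fit(X[current], y)
        rank = _importance_ranking(est, X[current], y)
        current = [f for f in current
                   if f != current[int(np.argmin(rank))]]
    profile = pd.DataFrame(rows).sort_values("size").reset_index(drop=True)
    best = profile["cv_r2"].max()
    if best > tie_tol:
        tied = profile[profile["cv_r2"] >= best - tie_tol]
    else:
        tied = profile  # nothing predictive: parsimony rules
    sel = list(tied.iloc[0]["features"])
    return sel, profile


def _checksum(arr):
    return hashlib.md5(np.round(np.asarray(arr, float), 12).tobytes()).hexdigest()


def train_model(X, y, method="rf", target_name="", rfe=True, seed=None,
                train_fraction=0.75, cv_folds=10, cv_repeats=3, grid=None,
                target_transform=None, n_trees=100) -> TrainedModel:
    """Partition, (optionally) select features, grid-search and evaluate.

    Metrics (via :func:`somkin.metrics.evaluate`) are computed on the model
    scale for both the training and the held-out test set; the AIC uses the
    test residuals with p = number of selected features.
    """
    if target_transform is None:
        target_transform = TARGET_TRANSFORMS.get(target_name, "identity")
    Xtr, Xte, ytr, yte, *_ = partition(X, y, train_fraction, seed)
    reg = KineticsParameterRegressor(
        method=method, rfe=rfe, target_transform=target_transform,
        cv_folds=cv_folds, cv_repeats=cv_repeats, grid=grid, n_trees=n_trees,
        random_state=seed)
    reg.fit(Xtr, ytr)
    p = max(len(reg.selected_features_), 1)
    ztr, zte = reg._ty(ytr), reg._ty(yte)
    ztr_hat = reg.estimator_.predict(reg._select(Xtr))
    zte_hat = reg.estimator_.predict(reg._select(Xte))
    train_metrics = _metrics.evaluate(ztr, ztr_hat, p=p)
    test_metrics = _metrics.evaluate(zte, zte_hat, p=p)
    return TrainedModel(
        method=method, target_name=target_name, regressor=reg,
        selected_features=list(reg.selected_features_),
        best_params=dict(reg.best_params_), cv_r2=reg.cv_r2_,
        train_metrics=train_metrics, test_metrics=test_metrics,
        aic=test_metrics["aic"], seed=seed, n_eval=len(yte),
        eval_checksum=_checksum(yte), X_test=Xte.reset_index(drop=True),
        y_test=np.asarray(yte))


def repeat_and_select(X, y, method="rf", n_repeats=100, seed=None,
                      **train_kw) -> tuple[TrainedModel, pd.DataFrame]:
    """Run ``n_repeats`` independent train/evaluate cycles; keep the best.

    Each run uses a fresh partition seed derived from ``seed``; the model
    maximizing held-out (validation) R² is returned together with the full
    per-run history.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    best, rows = None, []
    for i, s in enumerate(child_seeds):
        m = train_model(X, y, method=method, seed=int(s), **train_kw)
        rows.append({"run": i, "seed": int(s), "cv_r2": m.cv_r2,
                     "test_r2": m.test_metrics["r2"], "aic": m.aic})
        if best is None or m.test_metrics["r2"] > best.test_metrics["r2"]:
            best = m
    return best, pd.DataFrame(rows)


def compare_by_aic(models) -> list:
    """Rank models by ascending SSE-based AIC; the first entry wins.

    All models must have been evaluated on the same observation set.
    """
    models = list(models)
    if len({(m.n_eval, m.eval_checksum) for m in models}) > 1:
        raise ValueError("models were evaluated on different observation sets")
    return sorted(models, key=lambda m: m.aic)


def variable_importance(model: TrainedModel, X=None, y=None, n_repeats=10,
                        seed=None) -> pd.Series:
    """Relative importance (%) per feature; sums to 100.

    Defaults to the model's stored held-out set for permutation scoring.
    """
    if X is None:
        X, y = model.X_test, model.y_test
    return model.regressor.feature_importance(X, y, n_repeats=n_repeats,
                                              random_state=seed)


def partial_dependence(model, X, feature, grid_size=20) -> pd.DataFrame:
    """Partial dependence of the prediction on one selected feature.

    The feature is clamped to ``grid_size`` values spanning its observed
    range while all other covariates keep their data values; predictions are
    averaged at each grid point.  The x-axis is also reported normalized to
    0-1.
    """
    reg = model.regressor if isinstance(model, TrainedModel) else model
    if feature not in reg.selected_features_:
        raise ValueError(f"{feature!r} is not among the model's features")
    X = _as_frame(X).copy()
    lo, hi = X[feature].min(), X[feature].max()
    if hi == lo:
        raise ValueError(f"{feature!r} is constant; partial dependence undefined")
    grid = np.linspace(lo, hi, grid_size)
    pd_vals = np.empty(grid_size)
    for i, g in enumerate(grid):
        X[feature] = g
        pd_vals[i] = float(np.mean(reg.predict(X)))
    return pd.DataFrame({"x": grid, "x_norm": (grid - lo) / (hi - lo),
                         "yhat": pd_vals})
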