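"""Tuned nonlinear learners and the per-gridcell linear emergent constraint.

`ConstraintModel` is the regression learner at the centre of the framework:
one of three algorithms (random forest, RBF-kernel support vector regression,
gradient boosting) tuned by grid search over its canonical hyperparameter
axis with 10-fold cross-validation minimising RMSE, the folds shared across
candidates, then refit on the full spatial sample.

Search spaces (defaults):

* random forest — features considered per split (``mtry``) from 5 to 50 in
  steps of 1 (clipped to the number of features);
* gradient boosting — tree depth fixed at 3, learning rate fixed at 0.2,
  number of trees from 10 to 200 in steps of 5 (evaluated cheaply via staged
  predictions of a single 200-tree fit per fold);
* RBF SVR — 30 log-spaced cost candidates, each paired with a kernel width
  from the median-pairwise-distance heuristic on standardized features.

`GridwiseLinearEC` is the traditional emergent-constraint baseline: at every
grid cell an across-model ordinary least squares line between a historical
and a future quantity, evaluated at the observed historical value; cells with
a degenerate across-model relationship fall back to the unconstrained
multimodel mean.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.compose import TransformedTargetRegressor
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from ._rng import child_seed
from .features import kfold_split

__all__ = ["ALGORITHMS", "ConstraintModel", "GridwiseLinearEC", "median_heuristic_gamma"]

ALGORITHMS = ("random_forest", "svm_rbf", "gbm")


def median_heuristic_gamma(X: np.ndarray, max_samples: int = 500, seed: int = 0) -> float:
    """RBF gamma from the median pairwise squared distance of (a subsample of) X."""
    n = X.shape[0]
    if n > max_samples:
        idx = np.random.default_rng(seed).choice(n, max_samples, replace=False)
        X = X[idx]
    d2 = euclidean_distances(X, squared=True)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return 1.0 / med if med > 0 else 1.0


class ConstraintModel(RegressorMixin, BaseEstimator):
    """Grid-search-tuned regression learner for the observational constraint.

    Parameters
    ----------
    algorithm : {"random_forest", "svm_rbf", "gbm"}
    n_folds : int, default 10
        Cross-validation folds; candidates are scored on identical folds.
    seed : int, default 0
        Root seed for fold shuffling and tree randomness.
    rf_mtry : sequence of int, optional
        Candidate features-per-split values (default 5..50 step 1).
    rf_n_trees : int, default 100
        Forest size (fixed, not tuned).
    gbm_tree_counts : sequence of int, optional
        Candidate boosting lengths (default 10..200 step 5).
    svm_n_costs : int, default 30
        Number of log-spaced cost candidates in [2**-2, 2**12].

    Attributes
    ----------
    best_params_ : dict
        Winning hyperparameters (minimum CV RMSE).
    cv_rmse_, cv_r2_ : float
        Cross-validated RMSE of the winner and pooled CV R^2 (clipped to
        [0, 1]; ``cv_r2_raw_`` keeps the unclipped value).
    cv_results_ : list of (candidate, rmse)
    estimator_ : fitted sklearn regressor (refit on the full sample).
    """

    def __init__(
        self,
        algorithm: str = "random_forest",
        n_folds: int = 10,
        seed: int = 0,
        rf_mtry=None,
        rf_n_trees: int = 100,
        gbm_tree_counts=None,
        svm_n_costs: int = 30,
    ):
        self.algorithm = algorithm
        self.n_folds = n_folds
        self.seed = seed
        self.rf_mtry = rf_mtry
        self.rf_n_trees = rf_n_trees
        self.gbm_tree_counts = gbm_tree_counts
        self.svm_n_costs = svm_n_costs

    # ------------------------------------------------------------------
    def _folds(self, n: int) -> np.ndarray:
        return kfold_split(n, self.n_folds, self.seed)

    def fit(self, X, y):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        if np.std(y) == 0:
            warnings.warn("degenerate target with zero variance; fitting a constant predictor")
            self.estimator_ = DummyRegressor(strategy="mean").fit(X, y)
            self.best_params_ = {"constant": float(y[0]) if y.size else 0.0}
            self.cv_rmse_ = 0.0
            self.cv_r2_raw_ = 1.0
            self.cv_r2_ = 1.0
            self.cv_results_ = []
            return self
        folds = self._folds(X.shape[0])
        if self.algorithm == "gbm":
            best, results, cv_pred = self._tune_gbm(X, y, folds)
        elif self.algorithm == "random_forest":
            best, results, cv_pred = self._tune_rf(X, y, folds)
        else:
            best, results, cv_pred = self._tune_svm(X, y, folds)
        self.best_params_ = best
        self.cv_results_ = results
        resid = y - cv_pred
        self.cv_rmse_ = float(np.sqrt(np.mean(resid**2)))
        r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        self.cv_r2_raw_ = float(r2)
        self.cv_r2_ = float(np.clip(r2, 0.0, 1.0))
        self.estimator_ = self._make(best).fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(check_array(X))

    # ------------------------------------------------------------------
    def _make(self, params: dict):
        state = child_seed(self.seed, "fit") % (2**32)
        if self.algorithm == "random_forest":
            return RandomForestRegressor(
                n_estimators=self.rf_n_trees,
                max_features=params["mtry"],
                random_state=state,
                n_jobs=1,
            )
        if self.algorithm == "gbm":
            return GradientBoostingRegressor(
                n_estimators=params["n_trees"],
                max_depth=3,
                learning_rate=0.2,
                random_state=state,
            )
        # target standardization keeps the epsilon tube meaningful for
        # small-magnitude targets such as emission flux densities
        return TransformedTargetRegressor(
            regressor=make_pipeline(
                StandardScaler(),
                SVR(kernel="rbf", C=params["C"], gamma=params["gamma"]),
            ),
            transformer=StandardScaler(),
        )

    def _cv_rmse_grid(self, X, y, folds, candidates, make):
        """Shared-fold CV RMSE per candidate; returns per-candidate rmse and
        held-out predictions of the winner."""
        n = X.shape[0]
        preds = {i: np.zeros(n) for i in range(len(candidates))}
        for f in range(self.n_folds):
            test = folds == f
            for i, cand in enumerate(candidates):
                model = make(cand)
                model.fit(X[~test], y[~test])
                preds[i][test] = model.predict(X[test])
        rmses = [float(np.sqrt(np.mean((y - preds[i]) ** 2))) for i in range(len(candidates))]
        best_i = int(np.argmin(rmses))
        return rmses, best_i, preds[best_i]

    def _tune_rf(self, X, y, folds):
        cands = self.rf_mtry if self.rf_mtry is not None else range(5, 51)
        p = X.shape[1]
        mtry = sorted({min(int(m), p) for m in cands})
        rmses, best_i, cv_pred = self._cv_rmse_grid(
            X, y, folds, mtry, lambda m: self._make({"mtry": m})
        )
        results = [({"mtry": m}, r) for m, r in zip(mtry, rmses)]
        return {"mtry": mtry[best_i]}, results, cv_pred

    def _tune_svm(self, X, y, folds):
        gamma = median_heuristic_gamma(
            StandardScaler().fit_transform(X), seed=child_seed(self.seed, "gamma")
        )
        costs = np.logspace(-2, 12, self.svm_n_costs, base=2.0)
        rmses, best_i, cv_pred = self._cv_rmse_grid(
            X, y, folds, costs, lambda c: self._make({"C": float(c), "gamma": gamma})
        )
        results = [({"C": float(c), "gamma": gamma}, r) for c, r in zip(costs, rmses)]
        return {"C": float(costs[best_i]), "gamma": gamma}, results, cv_pred

    def _tune_gbm(self, X, y, folds):
        counts = list(self.gbm_tree_counts) if self.gbm_tree_counts is not None else list(range(10, 201, 5))
        counts = sorted(counts)
        n = X.shape[0]
        max_trees = counts[-1]
        # one max-length fit per fold; staged predictions score every count
        preds = {c: np.zeros(n) for c in counts}
        state = child_seed(self.seed, "fit") % (2**32)
        for f in range(self.n_folds):
            test = folds == f
            model = GradientBoostingRegressor(
                n_estimators=max_trees, max_depth=3, learning_rate=0.2, random_state=state
            ).fit(X[~test], y[~test])
            want = set(counts)
            for stage, yp in enumerate(model.staged_predict(X[test]), start=1):
                if stage in want:
                    preds[stage][test] = yp
        rmses = [float(np.sqrt(np.mean((y - preds[c]) ** 2))) for c in counts]
        best_i = int(np.argmin(rmses))
        results = [({"n_trees": c}, r) for c, r in zip(counts, rmses)]
        return {"n_trees": counts[best_i]}, results, preds[counts[best_i]]


class GridwiseLinearEC(BaseEstimator):
    """Per-gridcell across-model linear emergent constraint.

    fit(X, y) takes the member historical values ``X`` and member future
    values ``y``, both of shape (n_members, n_cells); predict(x_obs) evaluates
    each cell's regression line at the observed historical value.  Cells where
    the across-model variance of the historical value is (near) zero — or,
    when ``p_threshold`` is set, where the slope is insignificant — fall back
    to the unconstrained multimodel-mean future value.
    """

    def __init__(self, p_threshold: float | None = None, var_tol: float = 1e-25):
        self.p_threshold = p_threshold
        self.var_tol = var_tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape or X.ndim != 2:
            raise ValueError("X and y must both be (n_members, n_cells)")
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 members for an across-model line")
        xm = X.mean(axis=0)
        ym = y.mean(axis=0)
        sxx = ((X - xm) ** 2).sum(axis=0)
        sxy = ((X - xm) * (y - ym)).sum(axis=0)
        ok = sxx > self.var_tol * np.maximum(1.0, xm**2)
        slope = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        intercept = ym - slope * xm
        if self.p_threshold is not None:
            from scipy import stats

            resid = y - (intercept + slope * X)
            with np.errstate(divide="ignore", invalid="ignore"):
                s2 = (resid**2).sum(axis=0) / (n - 2)
                se = np.sqrt(s2 / np.where(ok, sxx, 1.0))
                t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf)
            p = 2 * stats.t.sf(np.abs(t), df=n - 2)
            ok = ok & (p <= self.p_threshold)
        self.ok_ = ok
        self.slope_ = np.where(ok, slope, 0.0)
        self.intercept_ = np.where(ok, intercept, ym)
        self.fallback_ = ym
        self.n_members_ = n
        return self

    def predict(self, x_obs):
        check_is_fitted(self, "slope_")
        x_obs = np.asarray(x_obs, dtype=float)
        out = self.intercept_ + self.slope_ * x_obs
        return np.where(self.ok_, out, self.fallback_)
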