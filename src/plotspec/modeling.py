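"""Regression families and the repeated stratified-split evaluation protocol.

Four model families predict a trait from plot-level vegetation-index features:
LR (one feature), MLR (all features, ordinary least squares), SMLR
(bidirectional stepwise selection minimizing Gaussian AIC, starting from the
full model) and PLSR (partial least squares, component count fixed or chosen
by seeded 5-fold cross-validation).

Evaluation follows the trial protocol: within each N-level stratum two thirds
of the plots (round half-up) go to training, the rest to test; features are
z-scored on the training set only; the split/fit/score cycle repeats 20 times
with consecutive seeds shared across families, and mean +/- sd of R-squared,
RMSE and MAE are reported for both sets.  R-squared is the squared sample
Pearson correlation between observed and predicted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression

from .errors import CollinearityError, DegenerateFitError, InvalidConfigError, SplitError
from .screening import TRAIT_COLUMNS

_RSS_FLOOR = 1e-300  # guards log(0) at exact interpolation; AIC -> very negative


# ---------------------------------------------------------------------------
# splitting and metrics
# ---------------------------------------------------------------------------

def stratified_split(plot_ids, strata, train_fraction: float = 2 / 3, seed: int = 0):
    """Seeded per-stratum split: round(fraction * size) to train, rest to test."""
    if not 0 < train_fraction < 1:
        raise SplitError("train_fraction must lie in (0, 1)")
    plot_ids = np.asarray(plot_ids)
    strata = np.asarray(strata)
    if plot_ids.shape != strata.shape:
        raise SplitError("plot_ids and strata must align")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for level in pd.unique(strata):
        members = plot_ids[strata == level]
        if len(members) < 2:
            raise SplitError(f"stratum {level!r} has fewer than 2 plots")
        n_train = int(np.floor(train_fraction * len(members) + 0.5))  # half-up
        perm = rng.permutation(len(members))
        train.extend(members[perm[:n_train]])
        test.extend(members[perm[n_train:]])
    return train, test


def regression_metrics(y_act, y_pred) -> dict:
    """R^2 (squared Pearson correlation), RMSE and MAE.

    R^2 is NaN (with a warning) when either vector is constant; RMSE/MAE are
    always returned.
    """
    a = np.asarray(y_act, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidConfigError("need equal-length vectors with n >= 2")
    err = a - p
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(a) == 0 or np.ptp(p) == 0:
        warnings.warn("R^2 undefined for constant observations or predictions")
        r2 = float("nan")
    else:
        r = np.corrcoef(a, p)[0, 1]
        r2 = float(r * r)
    return {"r2": r2, "rmse": rmse, "mae": mae}


# ---------------------------------------------------------------------------
# ordinary least squares with explicit collinearity diagnostics
# ---------------------------------------------------------------------------

def _design(X, intercept: bool):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X]) if intercept else X


def _collinear_columns(A, names):
    # columns that do not increase the incremental rank of the design
    bad, rank = [], 0
    for j in range(A.shape[1]):
        r = np.linalg.matrix_rank(A[:, : j + 1])
        if r == rank:
            bad.append(names[j] if j < len(names) else f"col{j}")
        rank = r
    return bad


class LinearModel(BaseEstimator, RegressorMixin):
    """OLS regression (optionally without intercept) on named features.

    Raises :class:`CollinearityError` naming the offending columns when the
    design matrix is rank deficient, instead of silently returning one of the
    infinitely many least-squares solutions.
    """

    def __init__(self, intercept: bool = True):
        self.intercept = intercept

    def fit(self, X, y, feature_names=None):
        names = list(feature_names) if feature_names is not None else _names_of(X)
        X = _matrix(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise InvalidConfigError("X and y lengths differ")
        A = _design(X, self.intercept)
        if np.isnan(A).any() or np.isnan(y).any():
            raise InvalidConfigError("missing values in the design or target")
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            offset = ["(intercept)"] if self.intercept else []
            raise CollinearityError(_collinear_columns(A, offset + names))
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        if self.intercept:
            self.intercept_, self.coef_ = float(beta[0]), beta[1:]
        else:
            self.intercept_, self.coef_ = 0.0, beta
        self.feature_names_ = names
        rss = float(np.sum((y - A @ beta) ** 2))
        self.rss_ = rss
        self.n_ = len(y)
        return self

    def predict(self, X):
        X = _matrix(X)
        return self.intercept_ + X @ self.coef_


def _names_of(X):
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    X = np.asarray(X)
    p = 1 if X.ndim == 1 else X.shape[1]
    return [f"x{j}" for j in range(p)]


def _matrix(X):
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def fit_ols(X, y, intercept: bool = True) -> LinearModel:
    return LinearModel(intercept=intercept).fit(X, y)


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC = n ln(RSS/n) + 2 (k + 1) for k predictors plus an intercept."""
    return n * np.log(max(rss, _RSS_FLOOR) / n) + 2 * (k + 1)


# ---------------------------------------------------------------------------
# stepwise AIC selection
# ---------------------------------------------------------------------------

class StepwiseAICRegressor(BaseEstimator, RegressorMixin):
    """Bidirectional stepwise OLS minimizing Gaussian AIC, from the full model.

    At every step the single add-or-drop move that most decreases the AIC is
    applied; the search stops when no move improves it.  Deterministic in the
    data: ties break toward the earliest candidate in drop-then-add,
    column-order enumeration.

    Attributes after fit: ``selected_features_``, ``model_`` (the OLS fit on
    the winning subset), ``aic_``, ``aic_full_``, ``aic_empty_``.
    """

    def __init__(self, intercept: bool = True):
        self.intercept = intercept

    def _aic_of(self, subset, X, y, names):
        n = len(y)
        if not subset:
            if not self.intercept:
                raise DegenerateFitError("empty model requires an intercept")
            rss = float(np.sum((y - y.mean()) ** 2))
            return gaussian_aic(rss, n, 0), None
        cols = [names.index(f) for f in subset]
        model = LinearModel(intercept=self.intercept).fit(X[:, cols], y, feature_names=subset)
        return gaussian_aic(model.rss_, n, len(subset)), model

    def fit(self, X, y, feature_names=None):
        names = list(feature_names) if feature_names is not None else _names_of(X)
        X = _matrix(X)
        y = np.asarray(y, dtype=float)
        current = list(names)
        aic, model = self._aic_of(current, X, y, names)
        self.aic_full_ = aic
        self.aic_empty_ = self._aic_of([], X, y, names)[0]
        while True:
            best = (aic, None)
            for f in current:  # drops first
                trial = [g for g in current if g != f]
                a, _ = self._aic_of(trial, X, y, names)
                if a < best[0]:
                    best = (a, trial)
            for f in names:  # then adds
                if f in current:
                    continue
                trial = current + [f]
                a, _ = self._aic_of(trial, X, y, names)
                if a < best[0]:
                    best = (a, trial)
            if best[1] is None:
                break
            current = best[1]
            aic = best[0]
        aic, model = self._aic_of(current, X, y, names)
        self.selected_features_ = current
        self.model_ = model
        self.aic_ = aic
        self.feature_names_ = names
        self._y_mean = float(y.mean())
        return self

    def predict(self, X):
        X = _matrix(X)
        if not self.selected_features_:
            return np.full(len(X), self._y_mean)
        cols = [self.feature_names_.index(f) for f in self.selected_features_]
        return self.model_.predict(X[:, cols])


# ---------------------------------------------------------------------------
# partial least squares with CV-selected component count
# ---------------------------------------------------------------------------

class PLSRegressionCV(BaseEstimator, RegressorMixin):
    """PLSR with the component count fixed or chosen by seeded 5-fold CV.

    Folds are stratified by the ``strata`` labels passed to :meth:`fit` (the
    trial's N levels) when given; the candidate count minimizing mean CV RMSE
    wins, with the smaller count breaking ties.  Scaling is left to the caller
    (the evaluation protocol z-scores on the training set).
    """

    def __init__(self, n_components="cv", cv_folds: int = 5, random_state: int = 0):
        self.n_components = n_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    @staticmethod
    def _max_components(X):
        Xc = X - X.mean(axis=0)
        return int(np.linalg.matrix_rank(Xc))

    def _folds(self, n, strata, rng):
        order = np.arange(n)
        if strata is not None:
            strata = np.asarray(strata)
            folds = [[] for _ in range(self.cv_folds)]
            for level in pd.unique(strata):
                members = rng.permutation(order[strata == level])
                for i, m in enumerate(members):
                    folds[i % self.cv_folds].append(m)
            return [np.asarray(sorted(f)) for f in folds if len(f)]
        perm = rng.permutation(order)
        return [np.asarray(sorted(f)) for f in np.array_split(perm, self.cv_folds) if len(f)]

    def fit(self, X, y, strata=None):
        X = _matrix(X)
        y = np.asarray(y, dtype=float)
        rank = self._max_components(X)
        if rank < 1:
            raise DegenerateFitError("X has rank 0 after centering")
        if self.n_components == "cv":
            rng = np.random.default_rng(self.random_state)
            folds = self._folds(len(y), strata, rng)
            candidates = range(1, rank + 1)
            cv_rmse = {}
            for k in candidates:
                errs = []
                for fold in folds:
                    tr = np.setdiff1d(np.arange(len(y)), fold)
                    k_fit = min(k, self._max_components(X[tr]))
                    m = PLSRegression(n_components=k_fit, scale=False).fit(X[tr], y[tr])
                    pred = m.predict(X[fold]).ravel()
                    errs.append(np.sqrt(np.mean((y[fold] - pred) ** 2)))
                cv_rmse[k] = float(np.mean(errs))
            self.cv_rmse_ = cv_rmse
            ncomp = min(cv_rmse, key=lambda k: (cv_rmse[k], k))
        else:
            ncomp = int(self.n_components)
            if not 1 <= ncomp <= rank:
                raise DegenerateFitError(f"n_components must lie in [1, {rank}], got {ncomp}")
        self.n_components_ = ncomp
        self.model_ = PLSRegression(n_components=ncomp, scale=False).fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(_matrix(X)).ravel()


# ---------------------------------------------------------------------------
# model specs and the 20-repeat protocol
# ---------------------------------------------------------------------------

MODEL_FAMILIES = ("lr", "mlr", "smlr", "plsr")


@dataclass
class ModelSpec:
    """One model run: family, feature columns ('index@stage'), target trait."""

    family: str
    features: object = "all"  # "all" or list of feature column names
    target: str = "yield"
    standardize: bool = True
    plsr_components: object = "cv"
    name: str | None = None

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise InvalidConfigError(f"family must be one of {MODEL_FAMILIES}")
        if self.target not in TRAIT_COLUMNS:
            raise InvalidConfigError(f"target must be one of {sorted(TRAIT_COLUMNS)}")
        if self.family == "lr" and (self.features == "all" or len(self.features) != 1):
            raise InvalidConfigError("lr uses exactly one feature")
        if self.name is None:
            self.name = f"{self.family}_{self.target}"


@dataclass
class EvaluationSummary:
    """Per-repeat and aggregated train/test metrics for one model spec."""

    spec: ModelSpec
    per_repeat: pd.DataFrame
    failures: list = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def aggregate(self) -> pd.DataFrame:
        cols = ["train_r2", "train_rmse", "train_mae", "test_r2", "test_rmse", "test_mae"]
        return pd.DataFrame({"mean": self.per_repeat[cols].mean(),
                             "std": self.per_repeat[cols].std(ddof=1)})


def _make_estimator(spec: ModelSpec, seed: int):
    if spec.family in ("lr", "mlr"):
        return LinearModel()
    if spec.family == "smlr":
        return StepwiseAICRegressor()
    return PLSRegressionCV(n_components=spec.plsr_components, random_state=seed)


def assemble_features(vi_table: pd.DataFrame, trait_table: pd.DataFrame, spec: ModelSpec):
    """Feature matrix (plots x 'index@stage'), target vector and strata labels."""
    from .indices import vi_wide

    wide = vi_wide(vi_table)
    if spec.features != "all":
        missing = [f for f in spec.features if f not in wide.columns]
        if missing:
            raise InvalidConfigError(f"features not in VI table: {missing}")
        wide = wide[list(spec.features)]
    col = TRAIT_COLUMNS[spec.target]
    tt = trait_table.set_index("plot_id")
    keep = tt.index[tt[col].notna()].intersection(wide.index)
    X = wide.loc[keep]
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise InvalidConfigError(f"missing feature cells in {bad}")
    y = tt.loc[keep, col].astype(float)
    strata = tt.loc[keep, "n_level"].astype(float)
    return X, y, strata


def repeated_evaluation(
    spec: ModelSpec,
    vi_table: pd.DataFrame,
    trait_table: pd.DataFrame,
    n_repeats: int = 20,
    base_seed: int = 0,
) -> EvaluationSummary:
    """Run the seeded 20-repeat stratified 2/3-train protocol for one spec.

    Repeat k uses split seed ``base_seed + k``, so different model families
    evaluated with the same ``base_seed`` see identical partitions.
    """
    X, y, strata = assemble_features(vi_table, trait_table, spec)
    ids = X.index.to_numpy()
    rows, failures = [], []
    for k in range(n_repeats):
        seed = base_seed + k
        try:
            train_ids, test_ids = stratified_split(ids, strata.loc[ids].to_numpy(), seed=seed)
            Xtr, Xte = X.loc[train_ids].to_numpy(), X.loc[test_ids].to_numpy()
            ytr, yte = y.loc[train_ids].to_numpy(), y.loc[test_ids].to_numpy()
            if spec.standardize:
                mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=0)
                sd = np.where(sd == 0, 1.0, sd)
                Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
            est = _make_estimator(spec, seed)
            if spec.family == "plsr":
                est.fit(Xtr, ytr, strata=strata.loc[train_ids].to_numpy())
            elif spec.family in ("smlr",):
                est.fit(Xtr, ytr, feature_names=list(X.columns))
            else:
                est.fit(Xtr, ytr, feature_names=list(X.columns))
            mtr = regression_metrics(ytr, est.predict(Xtr))
            mte = regression_metrics(yte, est.predict(Xte))
            rows.append(
                {
                    "seed": seed,
                    "train_r2": mtr["r2"], "train_rmse": mtr["rmse"], "train_mae": mtr["mae"],
                    "test_r2": mte["r2"], "test_rmse": mte["rmse"], "test_mae": mte["mae"],
                }
            )
        except Exception as exc:  # noqa: BLE001 - a failed repeat must not kill the run
            failures.append({"seed": seed, "error": f"{type(exc).__name__}: {exc}"})
    return EvaluationSummary(spec=spec, per_repeat=pd.DataFrame(rows), failures=failures)
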