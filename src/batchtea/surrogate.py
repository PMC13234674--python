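"""Surrogate-model pipeline over the scenario dataset.

Workflow: hold-out split (80/20), per-fold min-max scaling, multitask-LASSO
feature selection, six multi-output regressors screened by 5-fold
cross-validation (R^2, RMSE, MAPE per target and uniform-averaged),
randomized hyperparameter search for the boosted-tree model, learning
curves, and final hold-out evaluation.

All scaling and feature selection are fitted strictly inside each training
fold — validation rows never influence the scaler or the selected support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LinearRegression, MultiTaskLasso, MultiTaskLassoCV, Ridge
from sklearn.model_selection import KFold, ParameterSampler, train_test_split
from sklearn.multioutput import MultiOutputRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, PolynomialFeatures
from sklearn.svm import SVR
from scipy.stats import uniform as sp_uniform, randint as sp_randint
from xgboost import XGBRegressor

from .scenarios import FEATURE_COLUMNS, TARGET_COLUMNS, ScenarioDataset

__all__ = [
    "SplitPlan",
    "Scaler",
    "MetricsReport",
    "FeatureSelectionResult",
    "SearchSpace",
    "MODEL_NAMES",
    "split_train_test",
    "fit_scaler",
    "apply_scaler",
    "inverse_scaler",
    "select_features",
    "make_model",
    "train_models",
    "evaluate",
    "regression_metrics",
    "cross_validate_models",
    "tune_best",
    "learning_curve",
]


@dataclass(frozen=True)
class SplitPlan:
    train_fraction: float = 0.8
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


def split_train_test(dataset: ScenarioDataset | pd.DataFrame,
                     plan: SplitPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, seed-reproducible hold-out partition."""
    frame = dataset.frame if isinstance(dataset, ScenarioDataset) else dataset
    if len(frame) < 10:
        raise ValueError("dataset too small to split (need at least 10 rows)")
    train, test = train_test_split(frame, train_size=plan.train_fraction,
                                   random_state=plan.seed, shuffle=True)
    return train, test


# ---------------------------------------------------------------------------
# Min-max scaling (fitted on training data only)

@dataclass(frozen=True)
class Scaler:
    """Per-feature min-max parameters; maps the fitted range onto [0, 1].

    Constant features are passed through as 0 (with a warning at fit time).
    Data outside the fitted range maps outside [0, 1] — no clipping.
    """

    columns: tuple[str, ...]
    x_min: np.ndarray
    x_max: np.ndarray


def fit_scaler(train_features: pd.DataFrame) -> Scaler:
    x = train_features.to_numpy(dtype=float)
    x_min = x.min(axis=0)
    x_max = x.max(axis=0)
    constant = x_max <= x_min
    if constant.any():
        names = [c for c, flag in zip(train_features.columns, constant) if flag]
        warnings.warn(f"constant features passed through as 0: {names}",
                      RuntimeWarning, stacklevel=2)
    return Scaler(columns=tuple(train_features.columns), x_min=x_min, x_max=x_max)


def apply_scaler(scaler: Scaler, features: pd.DataFrame) -> pd.DataFrame:
    x = features[list(scaler.columns)].to_numpy(dtype=float)
    span = scaler.x_max - scaler.x_min
    safe = np.where(span > 0, span, 1.0)
    scaled = (x - scaler.x_min) / safe
    scaled[:, span <= 0] = 0.0
    return pd.DataFrame(scaled, columns=scaler.columns, index=features.index)


def inverse_scaler(scaler: Scaler, scaled: pd.DataFrame) -> pd.DataFrame:
    x = scaled[list(scaler.columns)].to_numpy(dtype=float)
    span = scaler.x_max - scaler.x_min
    out = x * np.where(span > 0, span, 0.0) + scaler.x_min
    return pd.DataFrame(out, columns=scaler.columns, index=scaled.index)


# ---------------------------------------------------------------------------
# Feature selection

@dataclass(frozen=True)
class FeatureSelectionResult:
    selected: tuple[str, ...]
    coefficients: dict[str, float]  # per-feature magnitude (L2 across targets)
    alpha: float


def select_features(train: pd.DataFrame, alpha: float | None = None,
                    seed: int = 0, cv_tolerance: float = 0.02,
                    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
                    target_columns: tuple[str, ...] = TARGET_COLUMNS,
                    ) -> FeatureSelectionResult:
    """Joint sparse linear selection over both targets (multitask LASSO).

    Features are min-max scaled and targets standardized before the fit so
    the shared penalty treats all columns comparably.  The regularization
    strength defaults to cross-validated selection with a parsimony rule:
    the sparsest strength whose CV error stays within ``cv_tolerance`` (in
    units of standardized-target variance, i.e. of 1 - R^2) of the best.
    The targets are deterministic functions of the inputs, so without the
    tolerance the CV optimum retains every variable with any effect, however
    economically negligible.
    """
    x = train[list(feature_columns)]
    y = train[list(target_columns)].to_numpy(dtype=float)
    if np.ptp(y, axis=0).min() <= 0:
        raise ValueError("degenerate (constant) target column")
    scaler = fit_scaler(x)
    xs = apply_scaler(scaler, x).to_numpy(dtype=float)
    y_std = y.std(axis=0)
    ys = (y - y.mean(axis=0)) / y_std

    if alpha is None:
        cv = MultiTaskLassoCV(cv=5, random_state=seed, alphas=60,
                              max_iter=5000).fit(xs, ys)
        mse = cv.mse_path_.mean(axis=1)                      # (n_alphas,)
        se = cv.mse_path_.std(axis=1) / np.sqrt(cv.mse_path_.shape[1])
        best = int(np.argmin(mse))
        # alphas_ is sorted descending: the smallest index within the
        # tolerance of the minimum is the sparsest acceptable model
        threshold = mse[best] + max(se[best], cv_tolerance)
        candidates = np.nonzero(mse <= threshold)[0]
        alpha = float(cv.alphas_[candidates.min()])
    model = MultiTaskLasso(alpha=alpha, max_iter=5000).fit(xs, ys)
    mags = np.linalg.norm(model.coef_, axis=0)  # coef_: (n_targets, n_features)
    selected = tuple(c for c, m in zip(feature_columns, mags) if m > 0.0)
    return FeatureSelectionResult(
        selected=selected,
        coefficients={c: float(m) for c, m in zip(feature_columns, mags)},
        alpha=float(alpha),
    )


# ---------------------------------------------------------------------------
# The six screened regressors

MODEL_NAMES: tuple[str, ...] = (
    "linear_regression", "knn", "random_forest",
    "polynomial_ridge", "svr", "xgboost",
)


def make_model(name: str, seed: int = 0) -> Pipeline:
    """One of the six screened techniques as a min-max-scaled multi-output
    pipeline with library-default hyperparameters."""
    if name == "linear_regression":
        est = LinearRegression()
    elif name == "knn":
        est = KNeighborsRegressor()
    elif name == "random_forest":
        est = RandomForestRegressor(random_state=seed)
    elif name == "polynomial_ridge":
        # degree-2 polynomial features with a ridge penalty
        return Pipeline([
            ("scale", MinMaxScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("model", MultiOutputRegressor(Ridge())),
        ])
    elif name == "svr":
        est = SVR()
    elif name == "xgboost":
        est = XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)
    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return Pipeline([
        ("scale", MinMaxScaler()),
        ("model", MultiOutputRegressor(est)),
    ])


def train_models(train: pd.DataFrame, features: tuple[str, ...],
                 seed: int = 0,
                 target_columns: tuple[str, ...] = TARGET_COLUMNS,
                 ) -> dict[str, Pipeline]:
    """Fit all six techniques on the training rows."""
    if len(features) < 2:
        raise ValueError("need at least two features")
    x = train[list(features)]
    y = train[list(target_columns)]
    fitted = {}
    for name in MODEL_NAMES:
        model = make_model(name, seed=seed)
        try:
            model.fit(x, y)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"{name}: singular design; try a lower polynomial degree"
            ) from exc
        fitted[name] = model
    return fitted


# ---------------------------------------------------------------------------
# Metrics

def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       zero_tol: float = 1e-9) -> dict[str, float]:
    """R^2, RMSE and MAPE for one target.

    MAPE excludes rows with |y| below ``zero_tol`` (their relative error is
    undefined); the exclusion count is reported under ``mape_excluded``.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    resid = y_true - y_pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    keep = np.abs(y_true) >= zero_tol
    mape = float(np.mean(np.abs(resid[keep] / y_true[keep])) * 100.0) if keep.any() else float("nan")
    return {"r2": r2, "rmse": rmse, "mape": mape,
            "mape_excluded": float((~keep).sum())}


@dataclass(frozen=True)
class MetricsReport:
    """Per-target and uniform-averaged metrics for a set of models."""

    per_target: dict[str, dict[str, dict[str, float]]]  # model -> target -> metrics
    target_columns: tuple[str, ...] = TARGET_COLUMNS

    def averaged(self) -> pd.DataFrame:
        """Uniform average of each metric over the targets, per model."""
        rows = {}
        for model, targets in self.per_target.items():
            rows[model] = {
                m: float(np.mean([targets[t][m] for t in self.target_columns]))
                for m in ("r2", "rmse", "mape")
            }
        return pd.DataFrame(rows).T

    def for_target(self, target: str) -> pd.DataFrame:
        return pd.DataFrame({m: t[target] for m, t in self.per_target.items()}).T


def evaluate(models: dict[str, Pipeline], data: pd.DataFrame,
             features: tuple[str, ...],
             target_columns: tuple[str, ...] = TARGET_COLUMNS) -> MetricsReport:
    """Score fitted models on a data table (typically the hold-out set)."""
    x = data[list(features)]
    y = data[list(target_columns)].to_numpy(dtype=float)
    report: dict[str, dict[str, dict[str, float]]] = {}
    for name, model in models.items():
        pred = np.asarray(model.predict(x), dtype=float)
        report[name] = {t: regression_metrics(y[:, j], pred[:, j])
                        for j, t in enumerate(target_columns)}
    return MetricsReport(per_target=report, target_columns=target_columns)


def cross_validate_models(train: pd.DataFrame, features: tuple[str, ...],
                          seed: int = 0, folds: int = 5,
                          models: dict[str, Pipeline] | None = None,
                          target_columns: tuple[str, ...] = TARGET_COLUMNS,
                          ) -> MetricsReport:
    """Validation-fold metrics by k-fold cross-validation.

    Each fold refits the whole pipeline (scaler included) on the fold's
    training rows, so no validation information leaks into preprocessing.
    Metrics are averaged over folds, per target.
    """
    if models is None:
        models = {name: make_model(name, seed=seed) for name in MODEL_NAMES}
    x = train[list(features)].reset_index(drop=True)
    y = train[list(target_columns)].reset_index(drop=True).to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    report: dict[str, dict[str, dict[str, float]]] = {}
    for name, prototype in models.items():
        fold_metrics: dict[str, list[dict[str, float]]] = {t: [] for t in target_columns}
        for tr_idx, va_idx in kf.split(x):
            model = clone(prototype)
            model.fit(x.iloc[tr_idx], y[tr_idx])
            pred = np.asarray(model.predict(x.iloc[va_idx]), dtype=float)
            for j, t in enumerate(target_columns):
                fold_metrics[t].append(regression_metrics(y[va_idx, j], pred[:, j]))
        report[name] = {
            t: {m: float(np.mean([fm[m] for fm in fold_metrics[t]]))
                for m in ("r2", "rmse", "mape")}
            for t in target_columns
        }
    return MetricsReport(per_target=report, target_columns=target_columns)


def normalized_target_report(model: Pipeline, train: pd.DataFrame,
                             test: pd.DataFrame, features: tuple[str, ...],
                             target_columns: tuple[str, ...] = TARGET_COLUMNS,
                             ) -> pd.DataFrame:
    """Hold-out RMSE on min-max normalized targets, next to the normalized
    target standard deviation.

    Rescaling both targets onto [0, 1] (parameters from the training rows)
    makes the error of the two differently-scaled outputs directly
    comparable: an RMSE well below the normalized standard deviation means
    the model explains most of the target's variability.
    """
    y_train = train[list(target_columns)].to_numpy(dtype=float)
    y_test = test[list(target_columns)].to_numpy(dtype=float)
    lo, hi = y_train.min(axis=0), y_train.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    pred = np.asarray(model.predict(test[list(features)]), dtype=float)
    rows = []
    for j, t in enumerate(target_columns):
        y_n = (y_test[:, j] - lo[j]) / span[j]
        p_n = (pred[:, j] - lo[j]) / span[j]
        rows.append({"target": t,
                     "rmse_normalized": float(np.sqrt(np.mean((y_n - p_n) ** 2))),
                     "std_normalized": float(y_n.std())})
    return pd.DataFrame(rows).set_index("target")


# ---------------------------------------------------------------------------
# Randomized search and learning curves

@dataclass(frozen=True)
class SearchSpace:
    """Printed search intervals for the boosted-tree model."""

    n_estimators: tuple[int, int] = (50, 300)
    max_depth: tuple[int, int] = (3, 30)
    learning_rate: tuple[float, float] = (0.001, 0.1)
    subsample: tuple[float, float] = (0.3, 1.0)
    colsample_bytree: tuple[float, float] = (0.3, 1.0)
    iterations: int = 30
    folds: int = 5

    def distributions(self) -> dict:
        return {
            "model__estimator__n_estimators": sp_randint(self.n_estimators[0],
                                                         self.n_estimators[1] + 1),
            "model__estimator__max_depth": sp_randint(self.max_depth[0],
                                                      self.max_depth[1] + 1),
            "model__estimator__learning_rate": sp_uniform(
                self.learning_rate[0], self.learning_rate[1] - self.learning_rate[0]),
            "model__estimator__subsample": sp_uniform(
                self.subsample[0], self.subsample[1] - self.subsample[0]),
            "model__estimator__colsample_bytree": sp_uniform(
                self.colsample_bytree[0], self.colsample_bytree[1] - self.colsample_bytree[0]),
        }


def _mean_cv_r2(model: Pipeline, x: pd.DataFrame, y: np.ndarray,
                folds: int, seed: int,
                target_columns: tuple[str, ...]) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr_idx, va_idx in kf.split(x):
        m = clone(model)
        m.fit(x.iloc[tr_idx], y[tr_idx])
        pred = np.asarray(m.predict(x.iloc[va_idx]), dtype=float)
        per_target = [regression_metrics(y[va_idx, j], pred[:, j])["r2"]
                      for j in range(len(target_columns))]
        scores.append(float(np.mean(per_target)))
    return float(np.mean(scores))


def tune_best(train: pd.DataFrame, features: tuple[str, ...],
              space: SearchSpace | None = None, seed: int = 0,
              target_columns: tuple[str, ...] = TARGET_COLUMNS,
              ) -> tuple[Pipeline, pd.DataFrame]:
    """Randomized hyperparameter search for the boosted-tree model.

    Samples ``space.iterations`` configurations uniformly from the printed
    intervals, scores each by k-fold mean uniform-averaged R^2, refits the
    best on the full training set, and returns (fitted model, search table).
    """
    space = space or SearchSpace()
    x = train[list(features)].reset_index(drop=True)
    y = train[list(target_columns)].reset_index(drop=True).to_numpy(dtype=float)
    sampler = ParameterSampler(space.distributions(), n_iter=space.iterations,
                               random_state=seed)
    records = []
    best_score, best_params = -np.inf, None
    for params in sampler:
        model = make_model("xgboost", seed=seed).set_params(**params)
        score = _mean_cv_r2(model, x, y, space.folds, seed, target_columns)
        records.append({**{k.split("__")[-1]: v for k, v in params.items()},
                        "cv_r2": score})
        if score > best_score:
            best_score, best_params = score, params
    best = make_model("xgboost", seed=seed).set_params(**best_params)
    best.fit(x, y)
    table = pd.DataFrame(records).sort_values("cv_r2", ascending=False)
    return best, table.reset_index(drop=True)


def learning_curve(model: Pipeline, train: pd.DataFrame,
                   features: tuple[str, ...],
                   sizes: np.ndarray | list[float] | None = None,
                   seed: int = 0, folds: int = 5,
                   target_columns: tuple[str, ...] = TARGET_COLUMNS,
                   ) -> pd.DataFrame:
    """Train/validation R^2 as the training-set size grows.

    For each size fraction, each fold trains on the first ``size`` rows of
    the (shuffled) fold-training split and validates on the untouched fold.
    """
    if sizes is None:
        sizes = np.linspace(0.1, 1.0, 8)
    sizes = np.asarray(sizes, dtype=float)
    if len(sizes) < 3:
        raise ValueError("need at least 3 size points")
    x = train[list(features)].reset_index(drop=True)
    y = train[list(target_columns)].reset_index(drop=True).to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for frac in sizes:
        tr_scores, va_scores = [], []
        for tr_idx, va_idx in kf.split(x):
            k = max(10, int(round(frac * len(tr_idx))))
            sub = tr_idx[:k]
            m = clone(model)
            m.fit(x.iloc[sub], y[sub])
            pred_tr = np.asarray(m.predict(x.iloc[sub]), dtype=float)
            pred_va = np.asarray(m.predict(x.iloc[va_idx]), dtype=float)
            tr_scores.append(np.mean([regression_metrics(y[sub, j], pred_tr[:, j])["r2"]
                                      for j in range(len(target_columns))]))
            va_scores.append(np.mean([regression_metrics(y[va_idx, j], pred_va[:, j])["r2"]
                                      for j in range(len(target_columns))]))
        rows.append({"train_fraction": float(frac),
                     "n_train": max(10, int(round(frac * (len(x) * (folds - 1) / folds)))),
                     "train_r2": float(np.mean(tr_scores)),
                     "train_r2_std": float(np.std(tr_scores)),
                     "validation_r2": float(np.mean(va_scores)),
                     "validation_r2_std": float(np.std(va_scores))})
    return pd.DataFrame(rows)
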