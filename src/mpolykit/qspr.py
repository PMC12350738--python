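"""QSPR regression of ADME-related properties on topological indices.

Ships a packaged table of 45 polycyclic drugs — identifiers, eleven
degree-based index columns and twelve physico-chemical property columns —
and the regression study around it: five model families (OLS, ridge,
lasso, elastic net, SVR), k-fold cross-validation with pooled out-of-fold
predictions, external hold-out validation, Pearson correlation matrices
with significance stars, and printable model equations.

Conventions:

* ``R`` is the Pearson correlation between observed values and (pooled)
  predictions; ``R2_corr`` is its square, always in [0, 1].
* ``R2`` is the coefficient of determination 1 - SSres/SStot, which can go
  negative out of sample.
* p-values are the two-sided t-test on Pearson r with n - 2 degrees of
  freedom.
* Predictors are standardized on training-partition statistics before
  regularized fits; linear coefficients are reported back on the raw scale.
* Default predictors are {mM2, ReZG3}; the Sch and Gut columns (opaque
  provenance) are never used unless explicitly requested.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import KFold, cross_val_predict, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

INDEX_COLUMNS = ("AZI", "M1", "M2", "mM2", "H", "ReZG3", "Sch", "Gut", "SDD", "I", "F")
PROPERTY_COLUMNS = ("MW", "EM", "PSA", "C", "BP", "EoV", "FP", "IoR", "MR", "P", "ST", "MV")
DEFAULT_PREDICTORS = ("mM2", "ReZG3")

MODEL_KINDS = ("ols", "ridge", "lasso", "elasticnet", "svr")
LINEAR_KINDS = ("ols", "ridge", "lasso", "elasticnet")

#: Defaults for the regularized fits; all overridable per call.
DEFAULT_HYPERPARAMS = {
    "ridge": {"alpha": 1.0},
    "lasso": {"alpha": 0.1},
    "elasticnet": {"alpha": 0.1, "l1_ratio": 0.5},
    "svr": {"kernel": "rbf", "C": 1.0, "epsilon": 0.1},
}

_FIXTURE_SHA256 = "78764794ffa72f7ee815a929cee195fc54d87d702b68fbc50554a5991b37da53"


class FixtureIntegrityError(RuntimeError):
    """The packaged drug table does not match its recorded checksum."""


class UnsupportedForNonlinear(ValueError):
    """Equation rendering requested for a model without linear coefficients."""


def load_fixture(verify: bool = True) -> pd.DataFrame:
    """Load the packaged 45-drug table.

    Index columns carry degree-based indices of the hydrogen-suppressed
    molecular graphs; property columns carry database-reported
    physico-chemical values, verbatim (units as printed in the source, no
    conversions applied).
    """
    raw = resources.files("mpolykit.data").joinpath("drug_table.csv").read_bytes()
    if verify and hashlib.sha256(raw).hexdigest() != _FIXTURE_SHA256:
        raise FixtureIntegrityError("packaged drug table failed its checksum")
    from io import BytesIO

    table = pd.read_csv(BytesIO(raw))
    assert len(table) == 45 and not table.isna().any().any()
    return table


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _make_model(model_kind: str, hyperparams: dict | None, seed: int) -> Pipeline:
    params = dict(DEFAULT_HYPERPARAMS.get(model_kind, {}))
    params.update(hyperparams or {})
    if model_kind == "ols":
        est = LinearRegression()
    elif model_kind == "ridge":
        est = Ridge(**params)
    elif model_kind == "lasso":
        est = Lasso(random_state=seed, **params)
    elif model_kind == "elasticnet":
        est = ElasticNet(random_state=seed, **params)
    elif model_kind == "svr":
        est = SVR(**params)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def _raw_scale_coefficients(pipe: Pipeline, predictors) -> tuple[dict[str, float], float]:
    """Undo the standardization: coefficients and intercept on raw units."""
    scaler: StandardScaler = pipe.named_steps["scale"]
    est = pipe.named_steps["model"]
    coef_std = np.asarray(est.coef_, dtype=float).ravel()
    raw = coef_std / scaler.scale_
    intercept = float(est.intercept_) - float(np.sum(raw * scaler.mean_))
    return dict(zip(predictors, raw.tolist())), intercept


def _pearson_with_p(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    if np.std(y_pred) == 0 or np.std(y_obs) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(y_obs, y_pred)
    return float(r), float(p)


@dataclass(frozen=True)
class FitReport:
    """Metrics (and, for linear kinds, raw-scale coefficients) of one fit."""

    model_kind: str
    target: str
    predictors: tuple[str, ...]
    context: str  # "in_sample" | "cv" | "external"
    n: int
    r: float
    r2_corr: float
    r2: float
    rmse: float
    p_value: float
    seed: int
    folds: int | None = None
    test_fraction: float | None = None
    coefficients: dict[str, float] | None = None
    intercept: float | None = None
    hyperparams: dict = field(default_factory=dict)

    def metrics_row(self) -> dict[str, float | str]:
        suffix = {"cv": "_cv", "external": "_external", "in_sample": ""}[self.context]
        return {
            "Model": self.model_kind,
            "Target": self.target,
            f"R{suffix}": self.r,
            f"R2_corr{suffix}": self.r2_corr,
            f"R2{suffix}": self.r2,
            f"RMSE{suffix}": self.rmse,
            f"p-value{suffix}": self.p_value,
        }


def _check_columns(table: pd.DataFrame, target: str, predictors) -> None:
    missing = [c for c in (target, *predictors) if c not in table.columns]
    if missing:
        raise KeyError(
            f"unknown column(s) {missing}; valid columns: {list(table.columns)}"
        )


def _metrics(y_obs, y_pred) -> dict[str, float]:
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant target: coefficient of determination undefined")
    r, p = _pearson_with_p(y_obs, y_pred)
    ss_res = float(np.sum((y_obs - y_pred) ** 2))
    return {
        "r": r,
        "r2_corr": r * r if np.isfinite(r) else float("nan"),
        "r2": 1.0 - ss_res / ss_tot,
        "rmse": float(np.sqrt(np.mean((y_obs - y_pred) ** 2))),
        "p_value": p,
    }


def fit_model(table: pd.DataFrame, target: str,
              predictors=DEFAULT_PREDICTORS, model_kind: str = "ols",
              hyperparams: dict | None = None, seed: int = 0) -> FitReport:
    """Fit on the full table; report in-sample metrics."""
    predictors = tuple(predictors)
    _check_columns(table, target, predictors)
    if len(table) <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    X = table[list(predictors)].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    pipe = _make_model(model_kind, hyperparams, seed)
    pipe.fit(X, y)
    m = _metrics(y, pipe.predict(X))
    coefs = intercept = None
    if model_kind in LINEAR_KINDS:
        coefs, intercept = _raw_scale_coefficients(pipe, predictors)
    return FitReport(model_kind, target, predictors, "in_sample", len(y),
                     m["r"], m["r2_corr"], m["r2"], m["rmse"], m["p_value"],
                     seed=seed, coefficients=coefs, intercept=intercept,
                     hyperparams=dict(hyperparams or {}))


def cv_metrics(table: pd.DataFrame, target: str,
               predictors=DEFAULT_PREDICTORS, model_kind: str = "ols",
               k: int = 5, hyperparams: dict | None = None,
               seed: int = 0) -> FitReport:
    """k-fold cross-validation; metrics on pooled out-of-fold predictions."""
    predictors = tuple(predictors)
    _check_columns(table, target, predictors)
    if not 2 <= k <= len(table):
        raise ValueError(f"fold count k={k} must be in [2, n={len(table)}]")
    X = table[list(predictors)].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    pipe = _make_model(model_kind, hyperparams, seed)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = cross_val_predict(pipe, X, y, cv=folds)
    m = _metrics(y, y_pred)
    return FitReport(model_kind, target, predictors, "cv", len(y),
                     m["r"], m["r2_corr"], m["r2"], m["rmse"], m["p_value"],
                     seed=seed, folds=k, hyperparams=dict(hyperparams or {}))


def external_metrics(table: pd.DataFrame, target: str,
                     predictors=DEFAULT_PREDICTORS, model_kind: str = "ols",
                     test_fraction: float = 0.2, hyperparams: dict | None = None,
                     seed: int = 0) -> FitReport:
    """Hold-out validation: fit on the training split, score the rest."""
    predictors = tuple(predictors)
    _check_columns(table, target, predictors)
    X = table[list(predictors)].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed
    )
    if len(y_tr) == 0 or len(y_te) == 0:
        raise ValueError("test fraction leaves an empty partition")
    pipe = _make_model(model_kind, hyperparams, seed)
    pipe.fit(X_tr, y_tr)
    m = _metrics(y_te, pipe.predict(X_te))
    coefs = intercept = None
    if model_kind in LINEAR_KINDS:
        coefs, intercept = _raw_scale_coefficients(pipe, predictors)
    return FitReport(model_kind, target, predictors, "external", len(y_te),
                     m["r"], m["r2_corr"], m["r2"], m["rmse"], m["p_value"],
                     seed=seed, test_fraction=test_fraction,
                     coefficients=coefs, intercept=intercept,
                     hyperparams=dict(hyperparams or {}))


# ---------------------------------------------------------------------------
# Correlation heatmap matrix
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Signed Pearson r, p-values, and significance stars.

    ``clipped()`` applies the display convention of flooring negative
    correlations at zero; the stored ``r`` always keeps signs.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def clipped(self) -> pd.DataFrame:
        return self.r.clip(lower=0.0)


def pearson_matrix(table: pd.DataFrame,
                   index_cols=INDEX_COLUMNS,
                   property_cols=PROPERTY_COLUMNS) -> CorrelationMatrix:
    """Index-by-property Pearson correlations with two-sided p-values.

    A zero-variance column yields NaN r and a ``var=0`` flag in the stars
    frame rather than an exception.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    r = pd.DataFrame(index=list(index_cols), columns=list(property_cols), dtype=float)
    p = r.copy()
    stars = pd.DataFrame("", index=list(index_cols), columns=list(property_cols))
    for ic in index_cols:
        for pc in property_cols:
            x = table[ic].to_numpy(dtype=float)
            y = table[pc].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r.loc[ic, pc] = np.nan
                p.loc[ic, pc] = np.nan
                stars.loc[ic, pc] = "var=0"
                continue
            rv, pv = stats.pearsonr(x, y)
            r.loc[ic, pc] = rv
            p.loc[ic, pc] = pv
            stars.loc[ic, pc] = _stars(pv)
    return CorrelationMatrix(r, p, stars)


# ---------------------------------------------------------------------------
# Equation rendering
# ---------------------------------------------------------------------------

def equation_report(fit: FitReport) -> str:
    """Render a fitted linear model as ``TARGET = a0 + (a1)*X1 + ...``.

    Coefficients print with 4 decimals; zero coefficients are retained so
    the predictor set stays visible.
    """
    if fit.coefficients is None or fit.intercept is None:
        raise UnsupportedForNonlinear(
            f"{fit.model_kind} has no linear coefficients to render"
        )
    terms = [f"{fit.intercept:.4f}"]
    terms += [f"({fit.coefficients[name]:.4f})*{name}" for name in fit.predictors]
    return f"{fit.target} = " + " + ".join(terms)
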