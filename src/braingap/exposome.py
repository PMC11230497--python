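"""Gradient-boosted regression of BAG on exposome and disparity predictors.

Country-level indicators (PM2.5, GINI, disease burdens, GII) are broadcast
to subjects and joined with subject-level flags (neurocognitive disorder
vs. control, sex, region).  Models are gradient-boosted regression trees
evaluated with repeated 10-fold cross-validation; feature importance is
assessed with a multi-method approach (held-out permutation importance and
mean-decrease-in-impurity, plus SHAP when the optional dependency is
installed), each with 99% confidence intervals.  A feature whose lower CI
bound does not exceed zero is flagged non-significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold, RepeatedKFold, train_test_split

from .evaluation import cohens_f2

__all__ = [
    "ExposomeDesign",
    "build_design",
    "fit_bag_regression",
    "multi_method_importance",
]

COUNTRY_PREDICTORS = ("GINI", "PM25", "communicable_burden", "noncommunicable_burden", "GII")

DEFAULT_PARAM_GRID = (
    {"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1},
    {"n_estimators": 200, "max_depth": 3, "learning_rate": 0.05},
    {"n_estimators": 300, "max_depth": 3, "learning_rate": 0.1},
)


@dataclass
class ExposomeDesign:
    X: pd.DataFrame
    y: np.ndarray
    predictors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.predictors:
            self.predictors = list(self.X.columns)
        if self.X.isna().any().any():
            raise ValueError("design matrix contains missing values")
        self.y = np.asarray(self.y, float)
        if len(self.y) != len(self.X):
            raise ValueError("outcome length does not match design")


def build_design(
    bag_table: pd.DataFrame,
    exposome: pd.DataFrame,
    *,
    predictors: tuple[str, ...] = COUNTRY_PREDICTORS,
    include_flags: bool = True,
) -> ExposomeDesign:
    """Join subject BAGs to country-level exposome values (ecological design).

    Subjects inherit their country's indicator values; a warning notes the
    clustered structure this induces.  ``has_disorder`` encodes the HC vs.
    {MCI, AD, bvFTD} contrast.
    """
    warnings.warn(
        "country-level predictors broadcast to subjects; observations are "
        "clustered within countries",
        stacklevel=2,
    )
    merged = bag_table.merge(exposome, on="country", how="left", validate="m:1")
    if merged[list(predictors)].isna().any().any():
        missing = sorted(set(bag_table["country"]) - set(exposome["country"]))
        raise ValueError(f"countries missing from exposome table: {missing}")
    X = merged[list(predictors)].copy()
    if include_flags:
        X["has_disorder"] = (merged["diagnosis"] != "HC").astype(float)
        if "sex" in merged:
            X["sex_female"] = (merged["sex"] == "F").astype(float)
        if "region" in merged:
            X["is_lac"] = (merged["region"] == "LAC").astype(float)
    return ExposomeDesign(X=X, y=merged["bag"].to_numpy())


def _select_params(
    design: ExposomeDesign,
    grid: tuple[dict, ...],
    n_folds: int,
    seed: int,
) -> dict:
    """Pick the grid entry with the lowest cross-validated RMSE."""
    best: tuple[float, dict] | None = None
    X, y = design.X.to_numpy(), design.y
    for params in grid:
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        sq = []
        for tr, te in cv.split(X):
            est = GradientBoostingRegressor(random_state=seed, **params)
            est.fit(X[tr], y[tr])
            sq.append(np.mean((est.predict(X[te]) - y[te]) ** 2))
        rmse = float(np.sqrt(np.mean(sq)))
        if best is None or rmse < best[0]:
            best = (rmse, params)
    assert best is not None
    return best[1]


def fit_bag_regression(
    design: ExposomeDesign,
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    param_grid: tuple[dict, ...] = DEFAULT_PARAM_GRID,
) -> tuple[GradientBoostingRegressor, pd.DataFrame]:
    """Repeated k-fold evaluation of a gradient-boosted BAG regression.

    Hyperparameters are selected by a small exhaustive grid on CV RMSE.
    Returns the final model refit on all rows and a metrics table with one
    row per repeat x fold (R^2, f^2, RMSE; ``n_folds * n_repeats`` rows).
    """
    if np.var(design.y) == 0:
        raise ValueError("constant outcome; regression undefined")
    if len(design.y) < 10 * n_folds:
        warnings.warn(
            f"only {len(design.y)} rows for {n_folds}-fold CV", stacklevel=2
        )
    params = _select_params(design, param_grid, n_folds, seed)
    X, y = design.X.to_numpy(), design.y

    rkf = RepeatedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    rows = []
    for k, (tr, te) in enumerate(rkf.split(X)):
        est = GradientBoostingRegressor(random_state=seed, **params)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        ss_res = float(np.sum((y[te] - pred) ** 2))
        ss_tot = float(np.sum((y[te] - y[te].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        rows.append(
            {
                "repeat": k // n_folds,
                "fold": k % n_folds,
                "r2": r2,
                "f2": cohens_f2(r2) if np.isfinite(r2) else np.nan,
                "rmse": float(np.sqrt(np.mean((y[te] - pred) ** 2))),
            }
        )
    final = GradientBoostingRegressor(random_state=seed, **params)
    final.fit(X, y)
    return final, pd.DataFrame(rows)


def _shap_importance(model, X: np.ndarray) -> np.ndarray | None:
    """Mean |SHAP| per feature via the optional external explainer."""
    try:
        import shap  # type: ignore
    except ImportError:
        return None
    explainer = shap.TreeExplainer(model)
    values = explainer.shap_values(X)
    return np.mean(np.abs(values), axis=0)


def multi_method_importance(
    model: GradientBoostingRegressor,
    design: ExposomeDesign,
    *,
    n_permutation_repeats: int = 100,
    n_mdi_bootstrap: int = 50,
    ci: float = 0.99,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation + MDI (+ optional SHAP) importance with CIs per predictor.

    Permutation importance: drop in held-out R^2 when one column is
    shuffled, repeated ``n_permutation_repeats`` times (CI across repeats).
    MDI: impurity-decrease shares from ``n_mdi_bootstrap`` refits on row
    resamples (CI across refits).  ``significant`` is true iff the lower CI
    bound is strictly positive.
    """
    rng = np.random.default_rng(seed)
    X, y = design.X.to_numpy(), design.y
    names = list(design.X.columns)
    alpha = (1.0 - ci) / 2.0
    rows = []

    # --- permutation importance on a held-out split
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.25, random_state=seed
    )
    est = clone(model)
    est.fit(X_tr, y_tr)
    base_pred = est.predict(X_te)
    ss_tot = float(np.sum((y_te - y_te.mean()) ** 2))
    base_r2 = 1.0 - float(np.sum((y_te - base_pred) ** 2)) / ss_tot
    for j, name in enumerate(names):
        drops = np.empty(n_permutation_repeats)
        X_perm = X_te.copy()
        for r in range(n_permutation_repeats):
            X_perm[:, j] = X_te[rng.permutation(len(X_te)), j]
            pred = est.predict(X_perm)
            r2 = 1.0 - float(np.sum((y_te - pred) ** 2)) / ss_tot
            drops[r] = base_r2 - r2
        lo, hi = np.quantile(drops, [alpha, 1.0 - alpha])
        rows.append(
            {"predictor": name, "method": "permutation",
             "mean": float(drops.mean()), "ci_low": float(lo),
             "ci_high": float(hi), "significant": bool(lo > 0)}
        )

    # --- MDI from bootstrap refits
    mdi = np.empty((n_mdi_bootstrap, len(names)))
    for b in range(n_mdi_bootstrap):
        idx = rng.integers(0, len(y), size=len(y))
        est_b = clone(model)
        est_b.fit(X[idx], y[idx])
        mdi[b] = est_b.feature_importances_
    for j, name in enumerate(names):
        lo, hi = np.quantile(mdi[:, j], [alpha, 1.0 - alpha])
        rows.append(
            {"predictor": name, "method": "mdi",
             "mean": float(mdi[:, j].mean()), "ci_low": float(lo),
             "ci_high": float(hi), "significant": bool(lo > 0)}
        )

    shap_vals = _shap_importance(model, X)
    if shap_vals is not None:
        for j, name in enumerate(names):
            rows.append(
                {"predictor": name, "method": "shap",
                 "mean": float(shap_vals[j]), "ci_low": np.nan,
                 "ci_high": np.nan, "significant": bool(shap_vals[j] > 0)}
            )
    return pd.DataFrame(rows)
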