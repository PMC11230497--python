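"""Brain-age-gap statistics: fit metrics, permutation tests, harmonization.

BAG (brain age gap) = predicted age - chronological age; positive values
mean an older-looking brain.  Group comparisons use two-sided subsample
permutation tests: each iteration draws equal-size subsamples from both
groups without replacement, pools them, permutes the labels and records the
null mean difference; the p-value uses the add-one estimator so it is never
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FitMetrics",
    "PermutationResult",
    "compute_bag",
    "compute_mde",
    "compute_fit_metrics",
    "cohens_f2",
    "permutation_group_test",
    "covariate_adjust",
    "harmonize_by_scanner",
]

_F2_CAP = 1e6


@dataclass
class FitMetrics:
    rmse: float
    r2: float
    pearson_r: float
    cohens_f2: float
    mde: float
    n: int


@dataclass
class PermutationResult:
    observed_diff: float
    n_iterations: int
    subsample_size: int
    p_two_sided: float
    null_mean: float
    null_sd: float
    null_quantiles: dict[float, float]
    seed: int | None


def compute_bag(preds: pd.DataFrame) -> pd.DataFrame:
    """Add a ``bag`` column (y_hat - y) to a prediction table."""
    out = preds.copy()
    out["bag"] = out["y_hat"] - out["y"]
    return out


def compute_mde(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean directional error: mean of sign(y_hat - y) over subjects.

    +1 when every prediction overshoots, -1 when every prediction
    undershoots, near 0 for balanced errors.
    """
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.size == 0:
        raise ValueError("need at least one prediction")
    return float(np.mean(np.sign(y_hat - y)))


def cohens_f2(r2: float) -> float:
    """Effect size f^2 = R^2 / (1 - R^2), capped for R^2 -> 1."""
    if r2 >= 1.0:
        return _F2_CAP
    return min(r2 / (1.0 - r2), _F2_CAP)


def compute_fit_metrics(y: np.ndarray, y_hat: np.ndarray) -> FitMetrics:
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.size < 2:
        raise ValueError("need at least 2 predictions")
    if np.var(y) == 0:
        raise ValueError("zero variance in chronological age; R^2 undefined")
    resid = y - y_hat
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    r = float(np.corrcoef(y, y_hat)[0, 1]) if np.var(y_hat) > 0 else 0.0
    return FitMetrics(
        rmse=rmse,
        r2=r2,
        pearson_r=r,
        cohens_f2=cohens_f2(r2),
        mde=compute_mde(y, y_hat),
        n=int(y.size),
    )


def permutation_group_test(
    bag_a: np.ndarray,
    bag_b: np.ndarray,
    n_iterations: int = 5000,
    seed: int | None = None,
    subsample_size: int | None = None,
) -> PermutationResult:
    """Two-sided subsample permutation test for a group mean-BAG difference.

    ``observed_diff`` is the full-group mean difference (mean_a - mean_b).
    Each iteration resamples ``subsample_size`` values (default the smaller
    group size) from each group without replacement, pools them, permutes
    group labels and records the permuted difference.  The two-sided p-value
    is ``(1 + #{|null| >= |observed|}) / (1 + n_iterations)``.
    """
    a = np.asarray(bag_a, float)
    b = np.asarray(bag_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_iterations < 100:
        warnings.warn("fewer than 100 permutation iterations", stacklevel=2)
    m = subsample_size or min(a.size, b.size)
    m = min(m, a.size, b.size)
    rng = np.random.default_rng(seed)
    observed = float(a.mean() - b.mean())

    # vectorized: subsample without replacement via argsort of uniforms
    idx_a = np.argsort(rng.random((n_iterations, a.size)), axis=1)[:, :m]
    idx_b = np.argsort(rng.random((n_iterations, b.size)), axis=1)[:, :m]
    pooled = np.concatenate([a[idx_a], b[idx_b]], axis=1)  # (iters, 2m)
    perm = np.argsort(rng.random(pooled.shape), axis=1)
    shuffled = np.take_along_axis(pooled, perm, axis=1)
    null = shuffled[:, :m].mean(axis=1) - shuffled[:, m:].mean(axis=1)

    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_iterations)
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    return PermutationResult(
        observed_diff=observed,
        n_iterations=n_iterations,
        subsample_size=m,
        p_two_sided=float(p),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        null_quantiles={q: float(v) for q, v in zip(qs, np.quantile(null, qs))},
        seed=seed,
    )


def covariate_adjust(bags: np.ndarray, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Residualize BAGs on covariates with an intercept (pooled OLS).

    Collinear covariate columns are handled by a pseudoinverse fit with a
    warning; residuals remain orthogonal to every covariate column and sum
    to zero.
    """
    y = np.asarray(bags, float)
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates contain missing or non-finite values")
    design = np.column_stack([np.ones(len(y)), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "collinear covariates detected; using minimum-norm solution",
            stacklevel=2,
        )
    return y - design @ beta


def harmonize_by_scanner(bags: np.ndarray, scanner_labels: np.ndarray) -> np.ndarray:
    """Within-scanner max-abs scaling of BAGs into [-1, 1], sign preserved.

    Each scanner's values are divided by that scanner's maximum absolute
    BAG, so zero stays zero and positive/negative gaps keep their
    interpretation; all-zero scanners pass through unchanged.
    """
    y = np.asarray(bags, float)
    labels = np.asarray(scanner_labels)
    if y.shape != labels.shape:
        raise ValueError("bags and scanner labels must align")
    out = y.copy()
    for s in np.unique(labels):
        sel = labels == s
        scale = np.max(np.abs(y[sel]))
        if scale > 0:
            out[sel] = y[sel] / scale
    return out
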