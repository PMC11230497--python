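"""Higher-order interaction (O-information) matrices from multivariate time series.

The pairwise-vs-rest O-information of regions (i, j) treats the remaining
N-2 regions as a single joint block z and evaluates

    Omega(x, y, z) = H(x,y,z) - H(x,y) - H(x,z) - H(y,z) + H(x) + H(y) + H(z)

with all entropies estimated by the Gaussian-copula approach: each channel is
rank-transformed to uniform scores and mapped through the standard normal
quantile function, after which differential entropies follow in closed form
from the sample covariance.  Omega > 0 indicates redundancy-dominated
dependence (shared randomness), Omega < 0 synergy (collective constraints).
All entropies are in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "DegenerateChannelError",
    "RegionTimeSeries",
    "OmegaMatrix",
    "EntropyEstimate",
    "copula_transform",
    "gaussian_entropy",
    "o_information",
    "o_information_pair",
    "omega_matrix",
    "normalize_omega",
]

#: ridge added to near-singular covariances before taking log-determinants
_RIDGE = 1e-8

#: 0.5 * ln(2*pi*e), the per-dimension constant of Gaussian entropy
_HALF_LOG_2PIE = 0.5 * np.log(2.0 * np.pi * np.e)


class DegenerateChannelError(ValueError):
    """Raised when a channel is constant and therefore has no copula."""


@dataclass
class RegionTimeSeries:
    """A regions x samples matrix of parcellated brain activity.

    Parameters
    ----------
    values
        Array of shape ``(n_regions, n_samples)``.
    region_labels
        One label per region, in row order.
    modality
        ``"fMRI"`` or ``"EEG"``.
    tr
        Repetition time in seconds (fMRI).
    sampling_rate
        Sampling rate in Hz (EEG).
    """

    values: np.ndarray
    region_labels: list[str]
    modality: str = "fMRI"
    tr: float | None = None
    sampling_rate: float | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D regions x samples matrix")
        n_regions, n_samples = self.values.shape
        if len(self.region_labels) != n_regions:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n_regions} regions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if n_regions < 3:
            raise ValueError("need at least 3 regions")
        if n_samples <= n_regions:
            warnings.warn(
                f"{n_samples} samples for {n_regions} regions; covariance "
                "estimates may be unstable",
                stacklevel=2,
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class OmegaMatrix:
    """Symmetric matrix of pairwise-vs-rest O-information values (nats)."""

    omega: np.ndarray
    region_labels: list[str]
    normalized: bool = False
    normalization_constant: float = 0.0
    modality: str = "fMRI"
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        n = self.omega.shape[0]
        if self.omega.shape != (n, n):
            raise ValueError("omega must be square")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValueError("omega must be symmetric")
        if self.normalized and self.omega.size:
            if np.max(np.abs(self.omega)) > 1.0 + 1e-12:
                raise ValueError("normalized omega must lie in [-1, 1]")


@dataclass
class EntropyEstimate:
    """Gaussian differential entropy of a copula-transformed block."""

    value: float
    block_size: int
    covariance_log_det: float


def copula_transform(X: np.ndarray, region_labels: list[str] | None = None) -> np.ndarray:
    """Rank each row to (0, 1) and map through the normal quantile function.

    Ranks use the average convention for ties and are scaled by ``1/(n+1)`` so
    the uniform scores stay strictly inside (0, 1).  The result is invariant
    to strictly increasing transforms of each input row.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a variables x samples matrix")
    n = X.shape[1]
    ptp = X.max(axis=1) - X.min(axis=1)
    if np.any(ptp == 0):
        idx = int(np.argmax(ptp == 0))
        name = region_labels[idx] if region_labels else f"row {idx}"
        raise DegenerateChannelError(
            f"channel {name!r} is constant; copula transform undefined"
        )
    u = rankdata(X, method="average", axis=1) / (n + 1)
    return ndtri(u)


def gaussian_entropy(block: np.ndarray) -> EntropyEstimate:
    """Entropy of a k x n copula-transformed block: ``0.5 ln((2 pi e)^k det S)``.

    ``S`` is the sample covariance (ddof=1).  Singular covariances are
    regularized with a small ridge and a warning.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    k, n = block.shape
    if n <= k:
        warnings.warn(f"entropy of {k} variables from {n} samples", stacklevel=2)
    sigma = np.cov(block)
    sigma = np.atleast_2d(sigma)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular covariance; adding ridge", stacklevel=2)
        sigma = sigma + _RIDGE * np.eye(k)
        sign, logdet = np.linalg.slogdet(sigma)
    return EntropyEstimate(
        value=k * _HALF_LOG_2PIE + 0.5 * logdet,
        block_size=k,
        covariance_log_det=logdet,
    )


def o_information(X: np.ndarray, *, copula: bool = True) -> float:
    """O-information of all n rows of ``X`` (each row one variable).

    Computed as ``(n-2) H(X) + sum_j [H(X_j) - H(X_{-j})]``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("O-information needs at least 3 variables")
    G = copula_transform(X) if copula else X
    total = (n - 2) * gaussian_entropy(G).value
    for j in range(n):
        total += gaussian_entropy(G[j]).value
        total -= gaussian_entropy(np.delete(G, j, axis=0)).value
    return float(total)


def _pair_vs_rest(G: np.ndarray, i: int, j: int) -> float:
    """Naive entropy-sum Omega(x_i, x_j, rest) on copula data ``G``."""
    rest = [k for k in range(G.shape[0]) if k not in (i, j)]
    H = lambda rows: gaussian_entropy(G[rows]).value  # noqa: E731
    return float(
        H(list(range(G.shape[0])))  # H(x, y, z)
        - H([i, j])                 # H(x, y)
        - H([i] + rest)             # H(x, z)
        - H([j] + rest)             # H(y, z)
        + H([i])
        + H([j])
        + H(rest)                   # H(z)
    )


def o_information_pair(ts: RegionTimeSeries, i: int, j: int) -> float:
    """Omega(x_i, x_j, Z) with Z the joint block of all other regions (nats)."""
    n = ts.n_regions
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"region index out of range for {n} regions")
    if i == j:
        raise ValueError("i and j must differ")
    G = copula_transform(ts.values, ts.region_labels)
    return _pair_vs_rest(G, i, j)


def omega_matrix(ts: RegionTimeSeries) -> OmegaMatrix:
    """Pairwise-vs-rest O-information for every region pair.

    All seven entropy terms of every pair are sub-determinants of the one
    full sample covariance S.  Using the precision matrix P = S^-1 and the
    identity det(S_{-A}) = det(S) det(P_AA), the entry reduces to

        Omega_ij = 0.5 [ -ln(1 - rho_ij^2) + ln(1 - P_ij^2 / (P_ii P_jj)) ]

    i.e. mutual information minus a partial-correlation analogue.  This is
    algebraically identical to the naive per-pair entropy sums (tested to
    1e-8 against a brute-force oracle).
    """
    G = copula_transform(ts.values, ts.region_labels)
    sigma = np.cov(G)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular covariance; adding ridge", stacklevel=2)
        sigma = sigma + _RIDGE * np.eye(sigma.shape[0])
    prec = np.linalg.inv(sigma)

    d = np.sqrt(np.diag(sigma))
    rho = sigma / np.outer(d, d)
    pd = np.diag(prec)
    partial_sq = prec**2 / np.outer(pd, pd)

    with np.errstate(divide="ignore", invalid="ignore"):
        omega = 0.5 * (-np.log1p(-rho**2) + np.log1p(-partial_sq))
    np.fill_diagonal(omega, 0.0)
    omega = 0.5 * (omega + omega.T)  # remove residual asymmetry
    return OmegaMatrix(
        omega=omega,
        region_labels=list(ts.region_labels),
        normalized=False,
        modality=ts.modality,
        n_samples=ts.n_samples,
    )


def normalize_omega(m: OmegaMatrix) -> OmegaMatrix:
    """Scale by the maximum absolute off-diagonal entry so values lie in [-1, 1].

    Signs are preserved; an all-zero matrix passes through unchanged with
    normalization constant 0.
    """
    off = m.omega[~np.eye(m.omega.shape[0], dtype=bool)]
    c = float(np.max(np.abs(off))) if off.size else 0.0
    scaled = m.omega / c if c > 0 else m.omega.copy()
    return OmegaMatrix(
        omega=scaled,
        region_labels=list(m.region_labels),
        normalized=True,
        normalization_constant=c,
        modality=m.modality,
        n_samples=m.n_samples,
    )
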