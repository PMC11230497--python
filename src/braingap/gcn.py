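"""Two-layer graph-convolutional age regressor.

Forward pass for a graph with adjacency A and node features X:

    A_hat = D~^(-1/2) (A + I) D~^(-1/2),  D~ = diag(row sums of |A + I|)
    H1    = relu(A_hat X W1 + b1)          (dropout on H1 during training)
    H2    = A_hat H1 W2 + b2               (single output channel)
    y_hat = mean over nodes of H2

Degrees use absolute values because O-information edge weights are signed.
Trained with mean-squared-error loss and the Adam optimizer; hyperparameters
(learning rate, epoch count) are selected by grid search with 5-fold
cross-validation on the training side, after which the model is retrained on
the full training side.  Implemented directly on NumPy arrays with explicit
gradients so the pipeline has no deep-learning framework dependency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import BrainGraph, DatasetSplit, assign_bins

__all__ = [
    "GCNParams",
    "TrainingPlan",
    "TrainedModel",
    "normalize_adjacency",
    "forward",
    "train_with_grid_search",
    "predict_batch",
]

logger = logging.getLogger(__name__)


@dataclass
class GCNParams:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    dropout_rate: float = 0.5

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[1]

    def copy(self) -> "GCNParams":
        return GCNParams(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(),
            self.dropout_rate,
        )

    def as_vector_list(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]


@dataclass
class TrainingPlan:
    learning_rate_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4)
    epoch_grid: tuple[int, ...] = (50, 100, 200)
    k_folds: int = 5
    batch_size: int = 16
    hidden_dim: int = 32
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate_grid or not self.epoch_grid:
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class TrainedModel:
    params: GCNParams
    best_hyperparams: dict
    cv_table: pd.DataFrame
    training_log: list[float]
    region_labels: list[str]
    modality: str
    plan: TrainingPlan


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops; degrees from absolute weights."""
    A = np.asarray(A, dtype=float)
    A_loop = A + np.eye(A.shape[0])
    deg = np.abs(A_loop).sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A_loop * np.outer(d_inv_sqrt, d_inv_sqrt)


def forward(
    graph: BrainGraph,
    params: GCNParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Predicted age for one graph.  Deterministic when ``training`` is false."""
    A_hat = normalize_adjacency(graph.adjacency)
    X = np.asarray(graph.node_features, dtype=float)
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match W1 rows {params.W1.shape[0]}"
        )
    H1 = np.maximum(A_hat @ X @ params.W1 + params.b1, 0.0)
    if training:
        if rng is None:
            rng = np.random.default_rng()
        p = params.dropout_rate
        if p > 0:
            mask = rng.random(H1.shape) >= p
            H1 = H1 * mask / (1.0 - p)
    H2 = A_hat @ (H1 @ params.W2) + params.b2
    return float(H2.mean())


# ---------------------------------------------------------------------------
# vectorized training internals
# ---------------------------------------------------------------------------


def _stack(graphs: list[BrainGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute (A_hat, A_hat @ X, y) stacks; A_hat X is constant in training."""
    A_hat = np.stack([normalize_adjacency(g.adjacency) for g in graphs])
    M = np.stack(
        [Ah @ np.asarray(g.node_features, float) for Ah, g in zip(A_hat, graphs)]
    )
    y = np.array([g.target_age for g in graphs], dtype=float)
    return A_hat, M, y


def _init_params(feat_dim: int, plan: TrainingPlan, rng: np.random.Generator) -> GCNParams:
    h = plan.hidden_dim
    s1 = np.sqrt(2.0 / feat_dim)
    s2 = np.sqrt(2.0 / h)
    return GCNParams(
        W1=rng.normal(0.0, s1, size=(feat_dim, h)),
        b1=np.zeros(h),
        W2=rng.normal(0.0, s2, size=(h, 1)),
        b2=np.zeros(1),
        dropout_rate=plan.dropout_rate,
    )


class _Adam:
    def __init__(self, params: GCNParams, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params.as_vector_list()]
        self.v = [np.zeros_like(p) for p in params.as_vector_list()]

    def step(self, params: GCNParams, grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params.as_vector_list(), grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _batch_forward_backward(
    A_hat: np.ndarray,
    M: np.ndarray,
    y: np.ndarray,
    params: GCNParams,
    rng: np.random.Generator,
) -> tuple[float, list[np.ndarray]]:
    """MSE loss and gradients for one mini-batch (B, N, F)."""
    B, N, _ = M.shape
    Z1 = M @ params.W1 + params.b1
    H1 = np.maximum(Z1, 0.0)
    p = params.dropout_rate
    if p > 0:
        mask = (rng.random(H1.shape) >= p) / (1.0 - p)
        H1d = H1 * mask
    else:
        mask = None
        H1d = H1
    S = H1d @ params.W2                     # (B, N, 1)
    H2 = A_hat @ S + params.b2
    pred = H2.mean(axis=(1, 2))             # (B,)
    err = pred - y
    loss = float(np.mean(err**2))

    dpred = 2.0 * err / B                   # (B,)
    dH2 = (dpred / N)[:, None, None] * np.ones((1, N, 1))
    db2 = np.array([dH2.sum()])
    dS = np.matmul(np.transpose(A_hat, (0, 2, 1)), dH2)
    dW2 = np.einsum("bnh,bno->ho", H1d, dS)
    dH1d = dS @ params.W2.T
    dH1 = dH1d * mask if mask is not None else dH1d
    dZ1 = dH1 * (Z1 > 0)
    dW1 = np.einsum("bnf,bnh->fh", M, dZ1)
    db1 = dZ1.sum(axis=(0, 1))
    return loss, [dW1, db1, dW2, db2]


def _train(
    A_hat: np.ndarray,
    M: np.ndarray,
    y: np.ndarray,
    plan: TrainingPlan,
    lr: float,
    epochs: int,
    rng: np.random.Generator,
) -> tuple[GCNParams, list[float]]:
    params = _init_params(M.shape[2], plan, rng)
    opt = _Adam(params, lr)
    n = len(y)
    log: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, plan.batch_size):
            idx = order[start : start + plan.batch_size]
            loss, grads = _batch_forward_backward(
                A_hat[idx], M[idx], y[idx], params, rng
            )
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            opt.step(params, grads)
            epoch_loss += loss * len(idx)
        log.append(epoch_loss / n)
    return params, log


def _predict_stack(A_hat: np.ndarray, M: np.ndarray, params: GCNParams) -> np.ndarray:
    H1 = np.maximum(M @ params.W1 + params.b1, 0.0)
    H2 = A_hat @ (H1 @ params.W2) + params.b2
    return H2.mean(axis=(1, 2))


def _cv_folds(ages: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by equal-width age bins."""
    edges = np.linspace(ages.min(), ages.max() + 1e-9, k + 1)
    bins = assign_bins(ages, edges)
    fold = np.empty(len(ages), dtype=int)
    for b in np.unique(bins):
        members = rng.permutation(np.flatnonzero(bins == b))
        fold[members] = np.arange(len(members)) % k
    return fold


def train_with_grid_search(split: DatasetSplit, plan: TrainingPlan) -> TrainedModel:
    """Grid search (lr x epochs) with stratified 5-fold CV, then final retrain.

    Combinations whose training diverges are marked failed and excluded from
    selection; ties break toward the earlier grid entry.  Fully reproducible
    given ``plan.seed``.
    """
    if not split.train:
        raise ValueError("training set is empty")
    modalities = {g.modality for g in split.train + split.test}
    if len(modalities) > 1:
        raise ValueError(f"mixed modalities in one model: {sorted(modalities)}")
    labels = split.train[0].region_labels
    for g in split.train + split.test:
        if g.region_labels != labels:
            raise ValueError("inconsistent region label order across graphs")

    A_hat, M, y = _stack(split.train)
    master = np.random.default_rng(plan.seed)
    fold = _cv_folds(y, plan.k_folds, np.random.default_rng(master.integers(2**63)))

    rows = []
    best: tuple[float, dict] | None = None
    for lr in plan.learning_rate_grid:
        for epochs in plan.epoch_grid:
            fold_mse = []
            failed = False
            for f in range(plan.k_folds):
                tr, va = fold != f, fold == f
                if va.sum() == 0 or tr.sum() == 0:
                    continue
                rng = np.random.default_rng(plan.seed + hash((lr, epochs, f)) % 10**6)
                try:
                    params, _ = _train(
                        A_hat[tr], M[tr], y[tr], plan, lr, epochs, rng
                    )
                except FloatingPointError:
                    failed = True
                    break
                pred = _predict_stack(A_hat[va], M[va], params)
                fold_mse.append(float(np.mean((pred - y[va]) ** 2)))
            mean_mse = float(np.mean(fold_mse)) if fold_mse and not failed else np.nan
            sd_mse = float(np.std(fold_mse)) if fold_mse and not failed else np.nan
            rows.append(
                {"lr": lr, "epochs": epochs, "mean_val_mse": mean_mse,
                 "sd_val_mse": sd_mse, "failed": failed or not fold_mse}
            )
            if np.isfinite(mean_mse) and (best is None or mean_mse < best[0]):
                best = (mean_mse, {"lr": lr, "epochs": epochs})
    cv_table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("every hyperparameter combination failed")
    logger.info("grid search selected %s", best[1])

    final_rng = np.random.default_rng(plan.seed + 7)
    params, log = _train(
        A_hat, M, y, plan, best[1]["lr"], best[1]["epochs"], final_rng
    )
    return TrainedModel(
        params=params,
        best_hyperparams=best[1],
        cv_table=cv_table,
        training_log=log,
        region_labels=list(labels),
        modality=split.train[0].modality,
        plan=plan,
    )


def predict_batch(graphs: list[BrainGraph], model: TrainedModel) -> pd.DataFrame:
    """Deterministic predictions; refuses graphs with mismatched label order."""
    if not graphs:
        return pd.DataFrame(columns=["subject_id", "y", "y_hat"])
    for g in graphs:
        if g.region_labels != model.region_labels:
            raise ValueError(
                f"graph {g.subject_id} region label order does not match model"
            )
        if g.modality != model.modality:
            raise ValueError(
                f"graph modality {g.modality} does not match model {model.modality}"
            )
    A_hat, M, y = _stack(graphs)
    y_hat = _predict_stack(A_hat, M, model.params)
    return pd.DataFrame(
        {"subject_id": [g.subject_id for g in graphs], "y": y, "y_hat": y_hat}
    )
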