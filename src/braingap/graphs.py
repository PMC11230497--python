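"""Learning-ready graphs from O-information matrices.

A graph's weighted adjacency is the (normalized) Omega matrix itself and
node i's feature vector is row i of that same matrix.  The training set can
be enlarged by linear interpolation between age-adjacent matrices:

    M_t = (1 - alpha) M_1 + alpha M_2,   alpha = (a_t - a_1) / (a_2 - a_1)

applied identically to adjacency and features, train side only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hoi import OmegaMatrix
from .synthetic import CohortRecord

__all__ = [
    "BrainGraph",
    "DatasetSplit",
    "build_graph",
    "filter_invalid",
    "stratified_split",
    "augment_by_interpolation",
]

logger = logging.getLogger(__name__)


@dataclass
class BrainGraph:
    adjacency: np.ndarray
    node_features: np.ndarray
    target_age: float
    region_labels: list[str]
    subject_ref: CohortRecord | None = None
    modality: str = "fMRI"
    is_augmented: bool = False
    parent_ids: tuple[str, str] | None = None
    alpha: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def subject_id(self) -> str:
        if self.subject_ref is not None:
            return self.subject_ref.subject_id
        return f"aug-{self.parent_ids}" if self.parent_ids else "unknown"

    def is_finite(self) -> bool:
        return bool(
            np.all(np.isfinite(self.adjacency))
            and np.all(np.isfinite(self.node_features))
            and np.isfinite(self.target_age)
        )


@dataclass
class DatasetSplit:
    train: list[BrainGraph]
    test: list[BrainGraph]
    bin_edges: np.ndarray
    seed: int = 0


def build_graph(m: OmegaMatrix, record: CohortRecord) -> BrainGraph:
    """Adjacency = Omega; node i's features = Omega row i; target = age."""
    omega = np.asarray(m.omega, dtype=float)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega matrix must be square")
    if len(m.region_labels) != omega.shape[0]:
        raise ValueError("region label count does not match matrix dimension")
    return BrainGraph(
        adjacency=omega.copy(),
        node_features=omega.copy(),
        target_age=float(record.age),
        region_labels=list(m.region_labels),
        subject_ref=record,
        modality=m.modality,
    )


def filter_invalid(graphs: list[BrainGraph]) -> list[BrainGraph]:
    """Drop graphs with non-finite features, adjacency, or target; keep order."""
    kept = [g for g in graphs if g.is_finite()]
    removed = len(graphs) - len(kept)
    if removed:
        logger.info("filter_invalid removed %d of %d graphs", removed, len(graphs))
    return kept


def _age_bins(ages: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(np.min(ages)), float(np.max(ages))
    if lo == hi:
        hi = lo + 1e-9
    return np.linspace(lo, hi, n_bins + 1)


def assign_bins(ages: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Equal-width bin index per age; top edge inclusive."""
    idx = np.digitize(ages, edges[1:-1], right=False)
    return np.clip(idx, 0, len(edges) - 2)


def stratified_split(
    graphs: list[BrainGraph],
    train_fraction: float = 0.8,
    n_bins: int = 5,
    seed: int = 0,
) -> DatasetSplit:
    """Disjoint, exhaustive train/test partition stratified by equal-width age bins."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if len(graphs) < n_bins:
        raise ValueError(f"need at least {n_bins} graphs for {n_bins} bins")
    rng = np.random.default_rng(seed)
    ages = np.array([g.target_age for g in graphs])
    edges = _age_bins(ages, n_bins)
    bins = assign_bins(ages, edges)

    train: list[BrainGraph] = []
    test: list[BrainGraph] = []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if members.size == 0:
            logger.info("age bin %d is empty", b)
            continue
        order = rng.permutation(members)
        n_train = int(np.floor(train_fraction * members.size + 0.5))
        train.extend(graphs[i] for i in order[:n_train])
        test.extend(graphs[i] for i in order[n_train:])
    return DatasetSplit(train=train, test=test, bin_edges=edges, seed=seed)


def augment_by_interpolation(
    train: list[BrainGraph], n_new: int = 500, seed: int = 0
) -> list[BrainGraph]:
    """``n_new`` interpolated graphs from consecutive age-sorted training pairs.

    Each new sample picks a random age-adjacent pair with distinct ages,
    draws a target age uniformly inside the interval and interpolates both
    adjacency and features.  Augmented graphs are flagged and must never
    enter a test set.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training graphs")
    order = sorted(range(len(train)), key=lambda i: train[i].target_age)
    pairs = [
        (order[k], order[k + 1])
        for k in range(len(order) - 1)
        if train[order[k + 1]].target_age > train[order[k]].target_age
    ]
    if not pairs:
        raise ValueError("all training ages identical; no interpolation interval")

    rng = np.random.default_rng(seed)
    out: list[BrainGraph] = []
    for _ in range(n_new):
        i1, i2 = pairs[rng.integers(len(pairs))]
        g1, g2 = train[i1], train[i2]
        a1, a2 = g1.target_age, g2.target_age
        a_t = float(rng.uniform(a1, a2))
        alpha = (a_t - a1) / (a2 - a1)
        out.append(
            BrainGraph(
                adjacency=(1 - alpha) * g1.adjacency + alpha * g2.adjacency,
                node_features=(1 - alpha) * g1.node_features + alpha * g2.node_features,
                target_age=a_t,
                region_labels=list(g1.region_labels),
                subject_ref=None,
                modality=g1.modality,
                is_augmented=True,
                parent_ids=(g1.subject_id, g2.subject_id),
                alpha=alpha,
            )
        )
    logger.info("augmented %d -> +%d graphs", len(train), len(out))
    return out
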