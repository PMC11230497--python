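import warnings

import numpy as np
import pytest

from braingap import graphs, synthetic
from braingap.hoi import RegionTimeSeries, normalize_omega, omega_matrix


@pytest.fixture(scope="session")
def small_config():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synthetic.CohortConfig(
            n_subjects=60, n_regions=12, n_samples=200, n_scanners=2, seed=5
        )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.generate_cohort_table(small_config)


@pytest.fixture(scope="session")
def small_graphs(small_config, small_cohort):
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, rec in enumerate(small_cohort):
            ts = synthetic.simulate_subject_timeseries(
                rec, small_config, seed=small_config.seed + 1000 + k
            )
            out.append(graphs.build_graph(normalize_omega(omega_matrix(ts)), rec))
    return out


@pytest.fixture(scope="session")
def trained_small_model(small_graphs):
    """A quickly trained model shared by gcn/importance tests."""
    from braingap.gcn import TrainingPlan, train_with_grid_search

    split = graphs.stratified_split(small_graphs, 0.8, 4, seed=5)
    split.train += graphs.augment_by_interpolation(split.train, 80, seed=6)
    plan = TrainingPlan(
        learning_rate_grid=(1e-2,), epoch_grid=(60,), hidden_dim=8,
        batch_size=16, seed=5,
    )
    return train_with_grid_search(split, plan), split


def make_ts(values, modality="fMRI", rate=None, tr=None, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"ch{i}" for i in range(values.shape[0])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return RegionTimeSeries(
            values=values, region_labels=labels, modality=modality,
            tr=tr, sampling_rate=rate,
        )
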