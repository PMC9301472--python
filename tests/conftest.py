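import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from connpool.connectome import ConnectivityMatrix, proportional_threshold, standardize_matrix
from connpool.model import ModelConfig
from connpool.synth import SimulationConfig, simulate_cohort
from connpool.trainer import TrainConfig, init_params, make_folds, train


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_symmetric(rng, n, zero_diag=True):
    m = rng.standard_normal((n, n))
    m = (m + m.T) / 2.0
    if zero_diag:
        np.fill_diagonal(m, 0.0)
    return m


def processed_matrix(rng, n, sparsity=0.3, subject_id="s0"):
    """A thresholded + standardized random connectivity matrix."""
    cm = ConnectivityMatrix(random_symmetric(rng, n),
                            [f"roi_{i}" for i in range(n)], subject_id)
    return standardize_matrix(proportional_threshold(cm, sparsity))


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject, 12-ROI planted-signal cohort (direct mode)."""
    cfg = SimulationConfig(n_subjects=40, n_rois=12, support_size=6,
                           timepoints=60, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_trained():
    """A briefly trained n=8 model plus its cohort, for gradient tests."""
    # dense enough that no ROI is isolated: edges between two isolated
    # nodes sit exactly on a leaky-ReLU kink, where a gradient check
    # would measure subgradients instead of the derivative
    cfg = SimulationConfig(n_subjects=30, n_rois=8, support_size=4,
                           sparsity=0.6, seed=5)
    ds, truth = simulate_cohort(cfg)
    mc = ModelConfig(n=8, d=3, adjacency_mode="identity")
    tc = TrainConfig(lr0=1e-3, epochs=15, seed=5)
    split = make_folds(ds.subject_ids, 5, 5)[0]
    params, _ = train(ds, split, mc, tc)
    return ds, params, mc
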