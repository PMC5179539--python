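import numpy as np
import pytest

from beacongrn.synthio import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_fixture():
    """120-gene planted-regulon dataset shared by the faster tests."""
    cfg = SimulationConfig(n_genes=120, regulon_size=30, seed=17)
    expression, regulons, signs = simulate_expression(cfg)
    return cfg, expression, regulons, signs


@pytest.fixture(scope="session")
def default_fixture():
    """The full default study-shaped dataset (500 genes, 100 targets)."""
    cfg = SimulationConfig()
    expression, regulons, signs = simulate_expression(cfg)
    return cfg, expression, regulons, signs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def mann_whitney_auc(scores, labels) -> float:
    """Independent AUC oracle: pairwise positive-vs-negative comparison,
    ties credited 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels > 0]
    neg = scores[labels <= 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
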