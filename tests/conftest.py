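import numpy as np
import pytest

from fastz import SimTruth, genes_to_counts, simulate_counts


@pytest.fixture(scope="session")
def neutral_truth() -> SimTruth:
    """No selection, no adaptive substitutions."""
    return SimTruth(n_genes=500, gamma_mean_S=0.0, p_adaptive=0.0, seed=11)


@pytest.fixture(scope="session")
def neutral_pool(neutral_truth):
    return genes_to_counts(simulate_counts(neutral_truth))


@pytest.fixture(scope="session")
def default_truth() -> SimTruth:
    return SimTruth(n_genes=300, seed=23)


@pytest.fixture(scope="session")
def default_genes(default_truth):
    return simulate_counts(default_truth)
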