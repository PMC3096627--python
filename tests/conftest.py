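import numpy as np
import pytest

from npmvs import ExpressionMatrix, SimulationDesign, simulate_dataset


@pytest.fixture
def tiny_matrix():
    """2 genes x 4 samples, two conditions of 2."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2"],
        values=np.array([[8.0, 8.2, 9.0, 9.4], [7.0, 7.1, 7.2, 7.3]]),
        condition_of_sample=["control", "control", "treatment", "treatment"],
        sample_ids=["c1", "c2", "t1", "t2"],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small case-2 simulated dataset shared across tests."""
    design = SimulationDesign(n_genes=800, pi1=0.05, n_replicates=3, case=2)
    return simulate_dataset(design, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
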