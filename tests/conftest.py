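import numpy as np
import pandas as pd
import pytest

from kisflux import simulate


@pytest.fixture(scope="session")
def headline_truth():
    """Moderate-size ground truth under the headline preset."""
    return simulate.generate_truth(2000, "headline", seed=11)


@pytest.fixture(scope="session")
def small_truth():
    return simulate.generate_truth(50, "headline", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_kinetics():
    """Hand-built WT/mutant kinetics tables with known ratios."""
    wt = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "strain": "WT",
            "TR": [10.0, 4.0, 2.0],
            "RA": [10.0, 8.0, 2.0],
            "HL": [1.0, 2.0, 1.0],
        }
    )
    mut = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "strain": "mut",
            "TR": [5.0, 4.0, 1.0],
            "RA": [10.0, 8.0, 3.0],
            "HL": [2.0, 2.0, 3.0],
        }
    )
    return wt, mut
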