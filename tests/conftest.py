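import numpy as np
import pandas as pd
import pytest

from leukodeconv import simulate


@pytest.fixture(scope="session")
def toy_B() -> pd.DataFrame:
    """Well-conditioned 50-gene × 4-type signature matrix with disjoint markers."""
    return simulate.make_signature_matrix(50, 4, overlap=0.0, seed=11)


@pytest.fixture(scope="session")
def gene_universe() -> list[str]:
    return [f"u{i:03d}" for i in range(200)]


@pytest.fixture(scope="session")
def overlapping_sigs(gene_universe):
    """Three cell types; A and B share half their marker genes, C is disjoint."""
    return {
        "A": [set(gene_universe[:20])],
        "B": [set(gene_universe[10:30])],
        "C": [set(gene_universe[50:70])],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
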