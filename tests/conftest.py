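import numpy as np
import pandas as pd
import pytest

from holosym import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paired_counts():
    """Small paired-design count matrix with planted DE genes."""
    counts, design, truth = simulate.gen_counts(
        n_genes=300, frac_de=0.1, lfc=2.0, dispersion=0.1, seed=7)
    return counts, design, truth


@pytest.fixture
def toy_scores():
    """Ten genes with scores 1..10 (the hand-enumeration enrichment fixture)."""
    return pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(10)])
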