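import numpy as np
import pandas as pd
import pytest

from rsikit.io import ExpressionMatrix
from rsikit.signatures import rsi_signature, tcia_gene_set
from rsikit.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def sig():
    return rsi_signature()


@pytest.fixture(scope="session")
def tcia():
    return tcia_gene_set()


@pytest.fixture()
def small_matrix():
    """Deterministic 30-gene x 12-sample matrix containing the RSI genes."""
    rng = np.random.default_rng(1234)
    sig = rsi_signature()
    genes = list(sig.genes) + [f"G{i:02d}" for i in range(20)]
    data = rng.normal(7.0, 2.0, size=(len(genes), 12))
    return ExpressionMatrix(
        pd.DataFrame(data, index=genes, columns=[f"S{j}" for j in range(12)])
    )


@pytest.fixture(scope="session")
def cohort_small():
    """Small default-condition synthetic cohort shared across test modules."""
    return generate(SyntheticConfig(n_samples=120, n_background_genes=60, seed=5))
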