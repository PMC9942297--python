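import warnings

import numpy as np
import pandas as pd
import pytest

from genesieve.pipeline import run_synthetic_screen
from genesieve.synthetic import ClassEffect, SyntheticSpec

warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def small_screen():
    """A small but fully-trained synthetic screen shared across tests."""
    spec = SyntheticSpec(
        n_genes_per_class=40,
        cds_length_range=(300, 900),
        class_effect=ClassEffect(gc_shift=0.15, codon_bias=1.0, markov_alpha=0.2, tm_insert_prob=0.3),
        seed=5,
    )
    result, truth = run_synthetic_screen(spec, n_cycles=5, max_iter=200)
    return result, truth


def random_feature_frame(rng: np.random.Generator, n: int, n_features: int = 6) -> pd.DataFrame:
    """A random normalized feature matrix shaped like a preprocessed input."""
    idx = pd.MultiIndex.from_tuples(
        [(f"G{i // 2}", f"G{i // 2}.c{i % 2}") for i in range(n)], names=["gene_id", "cds_id"]
    )
    return pd.DataFrame(rng.random((n, n_features)),
                        columns=[f"f{j}" for j in range(n_features)], index=idx)
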