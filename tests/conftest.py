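import numpy as np
import pytest

from mirmint.data_io import ExpressionMatrix
from mirmint.synthetic_data import SynthConfig, generate


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 features x 6 samples (3 tumor / 3 normal), log2 scale."""
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["T1", "T2", "T3", "N1", "N2", "N3"],
        groups=["tumor"] * 3 + ["normal"] * 3,
        values=rng.normal(8.0, 1.0, size=(3, 6)),
        scale="log2",
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic bundle shared across test modules."""
    config = SynthConfig(
        n_mirnas=40,
        n_genes=300,
        n_de_mirnas=6,
        targets_per_de_mirna=3,
        n_terms=20,
        term_size_range=(8, 15),
        seed=11,
    )
    return generate(config)
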