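import numpy as np
import pandas as pd
import pytest

from comodule.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """The reference synthetic scenario: 3 modules over background noise."""
    cfg = SyntheticConfig(
        module_sizes=(100, 80, 60),
        module_trait_cor=(0.6, 0.3, 0.0),
        loading_range=(0.6, 0.95),
        n_background=400,
        n_deg=0,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_planted(planted_dataset):
    from comodule.model import WGCNA

    return WGCNA(planted_dataset.expr, planted_dataset.trait).fit()


def random_expr(rng, n_genes=20, n_samples=10, prefix="g"):
    vals = rng.standard_normal((n_genes, n_samples))
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
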