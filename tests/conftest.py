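import numpy as np
import pandas as pd
import pytest

from fgcn.io import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(
    values,
    condition,
    platform="continuous",
    name="test",
    gene_ids=None,
    region=None,
    traits=None,
):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    if traits is not None:
        traits = pd.DataFrame(traits, index=sample_ids)
    return ExpressionDataset(
        name=name,
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        condition=list(condition),
        platform=platform,
        region=region,
        traits=traits,
    )


@pytest.fixture
def small_dataset(rng):
    """8 genes x 12 samples, 6 disease / 6 control, continuous platform."""
    values = rng.normal(6.0, 1.0, size=(8, 12))
    condition = ["disease"] * 6 + ["control"] * 6
    return make_dataset(values, condition)


@pytest.fixture
def random_dataset(rng):
    """50 genes x 40 samples for brute-force oracle comparisons."""
    values = rng.normal(6.0, 1.0, size=(50, 40))
    condition = ["disease"] * 20 + ["control"] * 20
    return make_dataset(values, condition)
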