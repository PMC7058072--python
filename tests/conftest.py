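import numpy as np
import pandas as pd
import pytest

from causalnet.datasets import OmicsDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_chain_dataset(n=1000, beta=1.5, gamma=1.5, seed=0):
    """X -> Y1 -> Y2 linear chain with unit Gaussian noise."""
    r = np.random.default_rng(seed)
    x = r.standard_normal(n)
    y1 = beta * x + r.standard_normal(n)
    y2 = gamma * y1 + r.standard_normal(n)
    data = pd.DataFrame({"X1": x, "Y1": y1, "Y2": y2})
    layers = {"X1": "genotype", "Y1": "expression", "Y2": "expression"}
    return OmicsDataset(data=data, layers=layers)


def make_rare_gene(n=300, p=30, seed=5):
    """Rare-variant genotype block whose leading FPC tracks a latent dosage."""
    r = np.random.default_rng(seed)
    latent = r.gamma(2, 1, n)
    g = (r.random((n, p)) < (0.04 * latent[:, None] / latent.mean())).astype(float)
    pos = np.sort(r.uniform(0, 1, p))
    return g, pos
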