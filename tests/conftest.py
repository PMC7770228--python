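import numpy as np
import pytest

import varnet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_tensor(rng):
    """10 genes x 4 timepoints x 8 individuals of i.i.d. noise."""
    values = rng.standard_normal((10, 4, 8))
    genes = [f"g{i:02d}" for i in range(10)]
    return varnet.ExpressionTensor(values, genes, [0, 6, 12, 18])


@pytest.fixture
def planted_tensor(rng):
    """Two perfectly correlated genes on top of 8 noise genes, 14 individuals.

    The planted pair shares the exact same values (up to a monotone shift),
    so its Spearman rho is 1 at every timepoint.
    """
    values = rng.standard_normal((10, 12, 14))
    values[1] = values[0] * 2.0 + 1.0
    genes = [f"g{i:02d}" for i in range(10)]
    return varnet.ExpressionTensor(values, genes, list(range(0, 24, 2)))


def make_network(timepoints, edges):
    """Build a CoexpressionNetwork from {(a, b): support_mask} pairs."""
    net = varnet.CoexpressionNetwork(timepoints, {"route": "variability"})
    t = len(timepoints)
    for (a, b), mask in edges.items():
        mask = np.asarray(mask, dtype=bool)
        rho = np.where(mask, 0.9, np.nan)
        net.add_edge(a, b, varnet.EdgeSupport((a, b), mask, rho))
    return net
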