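import numpy as np
import pandas as pd
import pytest

from sigstrat.data import ExpressionMatrix, GeneSignature


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """10 genes x 5 samples of standard-normal log2 values."""
    return ExpressionMatrix(
        rng.normal(size=(10, 5)),
        [f"G{i}" for i in range(10)],
        [f"S{i}" for i in range(5)],
    )


@pytest.fixture
def small_sig():
    return GeneSignature("sig", ("G0", "G1", "G2", "G3"))


def make_expr(values, gene_prefix="G", sample_prefix="S"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{i}" for i in range(values.shape[1])],
    )


@pytest.fixture
def make_expr_fn():
    return make_expr


def planted_blobs(seed, n_per=30, d=4, sep=10.0, n_blobs=3):
    """Gaussian blobs (sigma 1) with centers at mutual distance exactly `sep`."""
    rng = np.random.default_rng(seed)
    # vertices of a regular simplex scaled to pairwise distance sep
    centers = np.zeros((n_blobs, d))
    for i in range(n_blobs):
        centers[i, i % d] = 1.0
    # regular simplex: distance between distinct e_i is sqrt(2)
    centers *= sep / np.sqrt(2)
    x = np.vstack([rng.normal(0, 1.0, (n_per, d)) + c for c in centers])
    labels = np.repeat(np.arange(n_blobs), n_per)
    return x, labels
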