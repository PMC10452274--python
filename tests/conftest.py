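import numpy as np
import pandas as pd
import pytest

from icbench import ExpressionMatrix, load_builtin_registry


@pytest.fixture(scope="session")
def registry():
    return load_builtin_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230814)


def make_expression(rng, n_genes=30, n_samples=10, genes=None, scale=20.0):
    """Random TPM-like matrix, optionally naming the leading genes."""
    names = [f"G{i:03d}" for i in range(n_genes)]
    if genes:
        for i, g in enumerate(genes):
            names[i] = g
    values = rng.gamma(shape=2.0, scale=scale, size=(n_genes, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            values, index=names, columns=[f"S{j}" for j in range(n_samples)]
        )
    )


@pytest.fixture()
def small_expr(rng):
    return make_expression(rng)
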