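import numpy as np
import pytest

import gfaqsar as g
from gfaqsar.datasets import DescriptorTable, LigandRecord


@pytest.fixture(scope="session")
def table2():
    return g.load_table2()


@pytest.fixture(scope="session")
def table3():
    return g.load_table3()


def random_table(n: int, p: int, seed: int, coef=None, noise_sd: float = 0.5,
                 intercept: float = 1.0) -> DescriptorTable:
    """Small independent-Gaussian table for oracle tests.

    ``coef`` maps 0-based column indices to true slopes; defaults to the
    first min(p, 2) columns with unit slopes.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if coef is None:
        coef = {j: 1.0 for j in range(min(p, 2))}
    y = intercept + sum(b * X[:, j] for j, b in coef.items()) + rng.normal(0, noise_sd, n)
    names = [f"x{j}" for j in range(p)]
    records = [
        LigandRecord(
            ligand_id=str(i + 1),
            descriptors={nm: float(X[i, j]) for j, nm in enumerate(names)},
            pic50_obs=float(y[i]),
        )
        for i in range(n)
    ]
    return DescriptorTable(schema=tuple(names), records=records, name="random")
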