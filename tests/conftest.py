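import numpy as np
import pytest

import ordagree as oa

LOG3 = np.log(3.0)


@pytest.fixture(scope="session")
def ua_design():
    """Solved null design: all adjacent log-odds-ratios log 3, homogeneous margins."""
    return oa.solve_design(250, [LOG3] * 4, "homogeneous")


@pytest.fixture
def rng():
    return np.random.default_rng(1729)


@pytest.fixture
def random_tables(rng):
    """Small strictly-positive random tables (no empty rows/columns)."""

    def make(I, n_tables=5, lam=6.0):
        tables = []
        while len(tables) < n_tables:
            t = rng.poisson(lam, size=(I, I)) + (rng.random((I, I)) < 0.5)
            if t.sum() and not (np.any(t.sum(0) == 0) or np.any(t.sum(1) == 0)):
                tables.append(t.astype(int))
        return tables

    return make
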