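import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from treemingle.pattern import MarkedPointPattern, Window


@pytest.fixture
def rng():
    return np.random.default_rng(20180614)


@pytest.fixture
def square_window():
    return Window(0, 0, 100, 100)


@pytest.fixture
def cross_pattern():
    """Centre tree with four arms at distance 1; centre species differs."""
    return MarkedPointPattern(
        x=np.array([10.0, 11.0, 9.0, 10.0, 10.0]),
        y=np.array([10.0, 10.0, 10.0, 11.0, 9.0]),
        species=np.array(["A", "B", "B", "B", "B"], dtype=object),
        dbh=np.array([20.0, 10.0, 10.0, 10.0, 10.0]),
        window=Window(0, 0, 20, 20),
    )


@pytest.fixture
def four_tree_pattern():
    """Two species, four stems in a 20 x 20 window; used for hand-computed
    pair sums."""
    return MarkedPointPattern(
        x=np.array([0.0, 1.0, 0.0, 10.0]),
        y=np.array([0.0, 0.0, 1.0, 10.0]),
        species=np.array(["A", "A", "B", "B"], dtype=object),
        dbh=np.array([15.0, 15.0, 15.0, 15.0]),
        window=Window(0, 0, 20, 20),
    )


@pytest.fixture
def monoculture(square_window):
    rng = np.random.default_rng(7)
    n = 20
    return MarkedPointPattern(
        x=rng.uniform(0, 100, n),
        y=rng.uniform(0, 100, n),
        species=np.array(["A"] * n, dtype=object),
        dbh=rng.uniform(6, 40, n),
        window=square_window,
    )
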