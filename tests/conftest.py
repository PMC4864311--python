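import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from uvkit import SpectraSimConfig, simulate_irradiation_series
from uvkit.molevol import ProteinAlignment


@pytest.fixture
def nm_grid():
    """Standard 1-nm wavelength grid, 250-700 nm."""
    return np.arange(250.0, 701.0, 1.0)


@pytest.fixture
def default_series():
    """One simulated irradiation series at the default conditions."""
    return simulate_irradiation_series(SpectraSimConfig(seed=0))


def conflict_free_quartet(n_columns: int = 200, seed: int = 0) -> ProteinAlignment:
    """4-taxon alignment in which every variable column is compatible with
    the split AB|CD: constant columns, (x,x,y,y) columns, and singleton
    differences only."""
    rng = np.random.default_rng(seed)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    cols = []
    for _ in range(n_columns):
        r = rng.random()
        if r < 0.5:
            x = rng.choice(letters)
            cols.append(x * 4)
        elif r < 0.8:
            x, y = rng.choice(letters, size=2, replace=False)
            cols.append(x + x + y + y)
        else:
            x, y = rng.choice(letters, size=2, replace=False)
            which = rng.integers(0, 4)
            col = [x] * 4
            col[which] = y
            cols.append("".join(col))
    rows = tuple("".join(c[i] for c in cols) for i in range(4))
    return ProteinAlignment(("A", "B", "C", "D"), rows)
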