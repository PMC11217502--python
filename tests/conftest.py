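import numpy as np
import pandas as pd
import pytest

from metstab import METTable


def make_table(values: np.ndarray, trait: str = "trait",
               genotypes=None, envs=None, percent=()) -> METTable:
    """Build a METTable from a G x E x R value array."""
    g, e, r = values.shape
    genotypes = genotypes or [f"G{i+1:02d}" for i in range(g)]
    envs = envs or [f"env{j+1}" for j in range(e)]
    frame = pd.DataFrame({
        "genotype": np.repeat(genotypes, e * r),
        "env": np.tile(np.repeat(envs, r), g),
        "rep": np.tile(np.arange(1, r + 1), g * e),
        "trait": trait,
        "value": values.ravel(),
    })
    return METTable(frame, percent_traits=percent)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_table(rng):
    """Random balanced 6 x 3 x 3 table."""
    return make_table(50 + 5 * rng.standard_normal((6, 3, 3)))


@pytest.fixture
def additive_table():
    """Genotype effect only: no env effect, no interaction, no noise."""
    g_eff = np.array([0.0, 2.0, -1.0, 5.0])
    vals = np.broadcast_to(10 + g_eff[:, None, None], (4, 3, 2)).copy()
    return make_table(vals)
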