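import numpy as np
import pandas as pd
import pytest

from sparsegp.synthetic_nam import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """9 families x 10 RILs, 4 environments, 300 markers."""
    config = SimConfig(
        n_families_g1=3,
        n_families_g2=3,
        n_families_g3=3,
        rils_per_family=10,
        n_markers=300,
        n_chromosomes=10,
        n_env=4,
        seed=11,
    )
    pop, pheno, effects = simulate_dataset(config)
    return config, pop, pheno, effects


@pytest.fixture()
def ril_panel_1755():
    """Id-only panel at full scale (no genotypes needed for design tests)."""
    return [f"RIL{i:04d}" for i in range(1755)]


def naive_pearson(x, y):
    """Textbook sum-formula Pearson correlation (independent oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx**2) * np.sqrt(n * (y * y).sum() - sy**2)
    return num / den
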