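import numpy as np
import pandas as pd
import pytest

from airmediate import GeneratorConfig, TimeSeriesTable, generate


def random_table(n: int = 50, seed: int = 0, moderated: bool = True) -> TimeSeriesTable:
    """Small random table with x, m, y and (optionally) w, z columns.

    Built with correlated Gaussian columns so mediation fits are
    non-degenerate but otherwise structureless.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(10.0, 3.0, n)
    w = 0.4 * x + rng.normal(0.0, 2.0, n)
    z = -0.5 * x + rng.normal(50.0, 4.0, n)
    m = 2.0 * x - 0.3 * w + rng.normal(0.0, 3.0, n)
    y = 1.5 * x + 0.8 * m + 0.1 * z + rng.normal(0.0, 2.0, n)
    cols = {"x": x, "m": m, "y": y}
    if moderated:
        cols.update({"w": w, "z": z})
    frame = pd.DataFrame(cols, index=pd.date_range("2020-01-01", periods=n, freq="D"))
    return TimeSeriesTable(frame)


@pytest.fixture
def small_table() -> TimeSeriesTable:
    return random_table(n=30, seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """One generated dataset at the default study conditions."""
    cfg = GeneratorConfig(seed=11)
    table, truth = generate(cfg)
    return cfg, table, truth
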