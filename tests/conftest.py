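import numpy as np
import pandas as pd
import pytest

from planktonet.prep import CountTable
from planktonet.synth import SynthConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Small seeded synthetic dataset shared across tests (read-only)."""
    cfg = SynthConfig(
        n_otus_per_table=10,
        n_direct_pairs=3,
        n_env_driven_pairs=3,
        missing_blocks={},
        seed=11,
    )
    tables, env, truth = simulate_dataset(cfg)
    return cfg, tables, env, truth


def make_table(counts, months=None, domain="bacteria", size_fraction="pico", prefix="otu"):
    counts = np.asarray(counts)
    n_otus, n_samples = counts.shape
    if months is None:
        months = pd.period_range("2004-01", periods=n_samples, freq="M")
    frame = pd.DataFrame(
        counts, index=[f"{prefix}{i}" for i in range(n_otus)], columns=months
    )
    return CountTable(counts=frame, domain=domain, size_fraction=size_fraction)
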