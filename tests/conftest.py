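import numpy as np
import pytest

from mnshape import SynthConfig, generate_dataset_A, generate_dataset_B
from mnshape.data import MNHistogram
from mnshape.pipeline import build_table


@pytest.fixture(scope="session")
def config():
    return SynthConfig()


@pytest.fixture(scope="session")
def table_A(config):
    """Features+outcomes table for a default synthetic homogeneous-vs-mixed set."""
    return build_table(generate_dataset_A(config, seed=20240101), "A")


@pytest.fixture(scope="session")
def table_B(config):
    """Features+outcomes table for a default synthetic x-ray-vs-neutron set."""
    return build_table(generate_dataset_B(config, seed=20240202), "B")


def random_histograms(n, rng, max_count=30):
    """Small random histograms with positive mean and variance."""
    out = []
    while len(out) < n:
        counts = rng.integers(0, max_count, size=6)
        if counts.sum() < 2:
            continue
        vals = np.repeat(np.arange(6), counts)
        if vals.mean() > 0 and vals.std() > 0:
            out.append(MNHistogram(tuple(int(c) for c in counts)))
    return out
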