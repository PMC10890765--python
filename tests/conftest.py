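import numpy as np
import pytest

from meripower import PilotSpec, generate_pilot


@pytest.fixture(scope="session")
def small_pilot():
    """A compact pilot dataset shared by read-only tests."""
    spec = PilotSpec(n_regions=120, n_bins_per_region=4, n_per_group=3, seed=42)
    return generate_pilot(spec)


@pytest.fixture(scope="session")
def small_region_counts(small_pilot):
    return small_pilot.to_region_counts()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
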