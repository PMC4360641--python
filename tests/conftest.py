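import numpy as np
import pytest

from trioexome.io import load_fixtures
from trioexome.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free 44-trio cohort with planted events (shared, read-only)."""
    return generate_cohort(SimulationConfig(seed=20240, depth_mean=None))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noise-free cohort for I/O round trips."""
    return generate_cohort(
        SimulationConfig(
            n_trios=4,
            n_sites=80,
            seed=77,
            n_planted_comp_het_genes=2,
            n_planted_hom_rec_genes=2,
            depth_mean=None,
        )
    )
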