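import numpy as np
import pytest

from ivtkit.synthdata import (
    gen_shape_counts,
    gen_structured_reactivity,
    random_hairpin_structure,
)

CONCENTRATIONS = np.logspace(-1, 3, 8)  # half-log ladder, 0.1-1000 ng/ml


@pytest.fixture(scope="session")
def concentrations():
    return CONCENTRATIONS


@pytest.fixture(scope="session")
def hairpin_100():
    return random_hairpin_structure(100, 3)


@pytest.fixture(scope="session")
def shape_run(hairpin_100):
    """One deterministic SHAPE simulation: truth profile + count tables."""
    profile, truth = gen_structured_reactivity(hairpin_100, 11)
    pairs, _ = gen_shape_counts(profile, seed=12)
    return profile, pairs
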