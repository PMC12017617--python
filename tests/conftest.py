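"""Shared fixtures: a fast synthetic subject small enough for repeated fits."""

import numpy as np
import pytest

from neuroinflux.datatypes import StudyConfig
from neuroinflux.synthetic import gen_subject


TINY_CONFIG = dict(n_volumes=32, burn_in=5.0, max_evaluations=12,
                   cohort_tag="test", subject_tag="s01")


@pytest.fixture(scope="session")
def tiny_subject():
    """4-region, 32-volume noise-free-observation subject (fast to simulate)."""
    return gen_subject(
        n_regions=4,
        truth={"alpha_abeta": 0.12, "alpha_tau": 0.08, "G_coupling": 0.5},
        config=StudyConfig(**TINY_CONFIG),
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
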