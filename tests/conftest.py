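"""Shared fixtures for the audpsych test suite."""

import numpy as np
import pytest

from audpsych import PsychometricFunction


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def observer():
    """A plain 2AFC logistic observer on a linear axis."""
    return PsychometricFunction(midpoint=-10.0, slope=0.8,
                                guess_rate=0.5, lapse_rate=0.02)


@pytest.fixture
def small_cohort():
    """A 12-subject cohort with its ground-truth sidecar."""
    from audpsych import generate_cohort
    return generate_cohort(n=12, seed=99)
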