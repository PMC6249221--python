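"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from shockadvice import SynthParams, gen_record_set, prepare_channel_stacks


@pytest.fixture(scope="session")
def small_record_set():
    """Six 8-segment records, 25% shockable — cheap shared raw dataset."""
    return gen_record_set(6, 8, 0.25, SynthParams(seed=42))


@pytest.fixture(scope="session")
def small_stacks(small_record_set):
    """Channel stacks for the small record set (preprocess + MVMD applied)."""
    return prepare_channel_stacks(small_record_set)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
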