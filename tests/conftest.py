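"""Shared fixtures: small deterministic recordings and session pairs."""

import numpy as np
import pytest

import dnfilter as dn


@pytest.fixture(scope="session")
def subject_pair():
    """One synthetic subject: jaw-clench (500 Hz) + oddball (250 Hz) sessions."""
    rec1, truth1, rec2, truth2 = dn.synthetic_subject(1)
    return rec1, truth1, rec2, truth2


@pytest.fixture(scope="session")
def short_session():
    """A 20 s jaw-clench-style recording, cheap enough for many tests."""
    spec = dn.session1_spec(seed=7)
    spec.duration_s = 20.0
    rec, truth = dn.synthesize_recording(spec)
    return rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
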