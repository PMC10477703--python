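"""Shared fixtures: small synthetic subjects generated at test time."""

import numpy as np
import pytest

from preictal.synthetic import SyntheticSubjectSpec, generate_subject


@pytest.fixture(scope="session")
def tiny_subject():
    """4-channel, 15000-s subject with two seizures; used by training tests."""
    spec = SyntheticSubjectSpec(
        duration_s=15000.0, seizure_onsets_s=[5000.0, 11000.0],
        n_channels=4, affected_channels=(0, 1), seed=3)
    record, annotations = generate_subject(spec)
    return spec, record, annotations


@pytest.fixture(scope="session")
def short_record():
    """22-channel, 60-s seizure-free record for I/O tests."""
    spec = SyntheticSubjectSpec(duration_s=60.0, seizure_onsets_s=[],
                                n_channels=22, seed=11)
    record, _ = generate_subject(spec)
    return record


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
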