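"""Shared fixtures: small hand-enumerable claims worlds.

The *toy world* has two citizens: u1 churned once in ID1 (A→B) and once in
ID2 (X→Y), never simultaneously, so co-occurrence chains all of u1's claims
together; u2 is stable.  The *twin world* has two citizens sharing one ID1
value, the canonical identifiability failure.
"""

import pytest

from vpid.claims_model import Claim, EnrollmentRecord, GroundTruth


@pytest.fixture
def toy_claims():
    return [
        Claim("c1", "2013-04", "A", "X"),
        Claim("c2", "2013-06", "B", "X"),
        Claim("c3", "2013-08", "B", "Y"),
        Claim("c4", "2013-05", "C", "Z"),
    ]


@pytest.fixture
def toy_enrollment():
    return [
        EnrollmentRecord("u1", "A", "X", "2013-04", "2013-05"),
        EnrollmentRecord("u1", "B", "X", "2013-06", "2013-07"),
        EnrollmentRecord("u1", "B", "Y", "2013-08", "2013-12"),
        EnrollmentRecord("u2", "C", "Z", "2013-04", "2013-12"),
    ]


@pytest.fixture
def toy_truth():
    return GroundTruth(mapping={"c1": "u1", "c2": "u1", "c3": "u1", "c4": "u2"})


@pytest.fixture
def twin_claims():
    return [
        Claim("t1", "2013-04", "D", "P"),
        Claim("t2", "2013-05", "D", "Q"),
    ]


@pytest.fixture
def twin_truth():
    return GroundTruth(mapping={"t1": "u3", "t2": "u4"})
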