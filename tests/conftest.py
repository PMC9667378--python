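"""Shared fixtures: small seeded synthetic cohorts and a DLD oracle."""

from __future__ import annotations

from functools import cache

import pytest

from fnmdlink.synthetic import ErrorModel, generate_cohort


@cache
def dld_oracle(a: str, b: str) -> int:
    """Independent recursive restricted Damerau-Levenshtein distance.

    Straight transcription of the definition over string suffixes, used
    as the oracle the production dynamic-programming code is checked
    against.
    """
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[0] == b[0] else 1
    best = min(dld_oracle(a[1:], b) + 1,
               dld_oracle(a, b[1:]) + 1,
               dld_oracle(a[1:], b[1:]) + cost)
    if len(a) > 1 and len(b) > 1 and a[0] == b[1] and a[1] == b[0]:
        best = min(best, dld_oracle(a[2:], b[2:]) + 1)
    return best


@pytest.fixture(scope="session")
def clean_cohort():
    """300-member cohort with no injected error."""
    return generate_cohort(300, ErrorModel.zero(), seed=101)


@pytest.fixture(scope="session")
def noisy_cohort():
    """400-member cohort under the default error model."""
    return generate_cohort(400, ErrorModel(), seed=101)
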