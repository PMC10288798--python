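"""Shared fixtures and deterministic hypothesis settings."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmejtools import Locus

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def repeat_locus():
    """Toy locus with a 3-nt tandem repeat (CAT CAT) flanking the cut region."""
    return Locus("repeat", "GGGCATCATGGG")


@pytest.fixture
def plain_locus():
    """Toy locus whose central deletion has a unique placement."""
    return Locus("plain", "AAACGTTT")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def random_locus(rng, length, alphabet="ACGT"):
    """Random toy locus; a reduced alphabet yields repeat-rich sequence."""
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=length)])


def oracle_placements(seq, start, end):
    """All equal-length placements producing the same edited sequence.

    Independent brute-force oracle for deletion normalization: enumerate
    every interval of the same length and compare edited strings directly.
    """
    length = end - start
    edited = seq[:start] + seq[end:]
    return [
        i
        for i in range(len(seq) - length + 1)
        if seq[:i] + seq[i + length:] == edited
    ]
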