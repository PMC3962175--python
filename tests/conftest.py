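import itertools
import logging

import pytest
from hypothesis import HealthCheck, settings

from simscreen import Fingerprint

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# index builds on fixtures with deliberate all-zero entries would otherwise
# spam warnings through the whole run
logging.getLogger("simscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def six_bit_fingerprints():
    """All 64 six-bit fingerprints, indexed by their integer bit pattern."""
    return [
        Fingerprint([(v >> i) & 1 for i in range(6)]) for v in range(64)
    ]


@pytest.fixture(scope="session")
def six_bit_pairs(six_bit_fingerprints):
    """Every ordered pair of 6-bit fingerprints with a defined Tanimoto
    (at least one one-bit between them): 64*64 − 1 = 4095 pairs."""
    return [
        (a, b)
        for a, b in itertools.product(six_bit_fingerprints, repeat=2)
        if a.popcount + b.popcount > 0
    ]


def assert_same_results(res_a, res_b, tol=1e-12):
    """Two query results must contain the same identifiers with similarities
    equal within ``tol``."""
    hits_a, hits_b = sorted(res_a.hits), sorted(res_b.hits)
    assert [i for i, _ in hits_a] == [i for i, _ in hits_b]
    for (_, sa), (_, sb) in zip(hits_a, hits_b):
        assert abs(sa - sb) <= tol
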