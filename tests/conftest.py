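from fractions import Fraction
from math import comb

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> Fraction:
    """Independent oracle: exact P(X >= k) by enumerating the pmf over the
    full support with rational arithmetic."""
    denom = comb(N, n)
    return sum(
        (Fraction(comb(K, i) * comb(N - K, n - i), denom) for i in range(k, min(n, K) + 1)),
        Fraction(0),
    )


def bh_oracle(pvalues):
    """Independent oracle: naive double-loop Benjamini-Hochberg step-up.

    q_i = min over j with p_j >= p_i of (p_j * m / rank_j), capped at 1,
    computed directly from the sorted definition without vectorization.
    """
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted_sorted = [None] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        q = pvalues[i] * m / (pos + 1)
        running_min = min(running_min, q)
        adjusted_sorted[pos] = min(running_min, 1.0)
    out = [None] * m
    for pos, i in enumerate(order):
        out[i] = adjusted_sorted[pos]
    return out


@pytest.fixture(scope="session")
def default_catalog():
    from sporeamg.io_ingest import load_default_catalog

    return load_default_catalog()
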