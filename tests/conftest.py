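import math
from fractions import Fraction

import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def hypergeom_tail_exact(k: int, N: int, K: int, n: int, upper: bool) -> Fraction:
    """Exact hypergeometric tail by enumeration of the support.

    Independent oracle: sums C(K, x) C(N-K, n-x) / C(N, n) over x >= k
    (upper) or x <= k (lower) with exact rational arithmetic.
    """
    total = math.comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(K, n)
    xs = range(k, hi + 1) if upper else range(lo, k + 1)
    return Fraction(sum(math.comb(K, x) * math.comb(N - K, n - x) for x in xs), total)


@pytest.fixture
def tail_oracle():
    return hypergeom_tail_exact
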