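import math

import numpy as np
import pytest

from boldcomplexity import basis_from_connectome, gen_connectome


def sampen_bruteforce(x, m: int, r: float) -> float:
    """Exhaustive template-pair sample entropy (independent oracle).

    Counts unordered template pairs over the first n−m start points for both
    template lengths, Chebyshev distance strictly below r, self-pairs
    excluded; −ln(A/B), NaN when either count is zero.
    """
    x = [float(v) for v in x]
    n = len(x)
    n_templates = n - m

    def count(length: int) -> int:
        total = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if all(abs(x[i + k] - x[j + k]) < r for k in range(length)):
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


@pytest.fixture(scope="session")
def connectome30():
    return gen_connectome(30, 0.3, seed=42)


@pytest.fixture(scope="session")
def basis30(connectome30):
    return basis_from_connectome(connectome30)


@pytest.fixture(scope="session")
def connectome20():
    return gen_connectome(20, 0.3, seed=99)


@pytest.fixture(scope="session")
def basis20(connectome20):
    return basis_from_connectome(connectome20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
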