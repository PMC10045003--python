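import numpy as np
import pytest

from cgsurv import ArchimedeanCopula, CensoredSample


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def random_sample(rng, n=None, with_pi=False) -> CensoredSample:
    """A random right-censored sample with ties possible."""
    if n is None:
        n = int(rng.integers(2, 30))
    # rounding induces tied times
    time = np.round(rng.exponential(size=n) + 0.05, 1)
    status = rng.integers(0, 2, size=n)
    if status.sum() == 0:
        status[rng.integers(n)] = 1
    pi = rng.normal(size=n) if with_pi else None
    return CensoredSample(time=time, status=status, pi=pi)


def random_copula(rng) -> ArchimedeanCopula:
    family = rng.choice(["clayton", "gumbel", "frank", "independence"])
    if family == "independence":
        return ArchimedeanCopula("independence")
    if family == "frank":
        alpha = float(rng.uniform(-20, 20))
        if abs(alpha) < 1e-3:
            alpha = 1.0
    else:
        alpha = float(rng.uniform(0.05, 20))
    return ArchimedeanCopula(family, alpha)
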