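import numpy as np
import pytest

from powermix import io
from powermix.types import CensoredSummary, IPHyper, PriorSpec


@pytest.fixture(scope="session")
def kevlar_summary() -> CensoredSummary:
    return io.kevlar_summary()


@pytest.fixture(scope="session")
def reference_hyper() -> IPHyper:
    return io.reference_hyper()


@pytest.fixture(scope="session")
def all_priors(reference_hyper) -> list[PriorSpec]:
    return [PriorSpec("uniform"), PriorSpec("jeffreys"),
            PriorSpec("informative", reference_hyper)]


def make_toy_summary(rng: np.random.Generator, max_censored: int = 3,
                     min_failures: int = 4) -> CensoredSummary:
    """Random small summary with enough failures for every moment order.

    ``min_failures >= 4`` keeps even the r = -2 moments well defined under
    the Jeffreys prior (gamma shape u_m > 2) and keeps quadrature easy.
    """
    us = rng.integers(min_failures, min_failures + 5, size=3)
    L = float(rng.uniform(0.2, 1.0))
    Ss = [float(u * L + rng.gamma(u, 1.0)) for u in us]
    M = int(rng.integers(0, max_censored + 1))
    return CensoredSummary(n=int(us.sum()) + M, log_inv_t=L,
                           u1=int(us[0]), u2=int(us[1]), u3=int(us[2]),
                           S1=Ss[0], S2=Ss[1], S3=Ss[2])


@pytest.fixture
def toy_summary_factory():
    return make_toy_summary
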