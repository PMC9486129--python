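import numpy as np
import pytest

from tsh2bind import (
    RateConstants,
    ReducedRateConstants,
    reduced_reference,
    zap70_reference,
)


@pytest.fixture
def ref_rates() -> RateConstants:
    return zap70_reference()


@pytest.fixture
def reduced_rates() -> ReducedRateConstants:
    return reduced_reference()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


def random_rates(rng: np.random.Generator) -> RateConstants:
    """A random admissible full-model parameter set (log-uniform rates)."""

    def lu(lo, hi):
        return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))

    return RateConstants(
        kf=lu(1e-5, 1e-2),
        kb=lu(1e-4, 1e-1),
        w1=float(rng.uniform(0.001, 1.0)),
        w2=float(rng.uniform(0.001, 1.0)),
        w3=float(rng.uniform(0.001, 1.0)),
        kb1=lu(1e-4, 1e-1),
        kb2=lu(1e-4, 1e-1),
        kb3=lu(1e-4, 1e-1),
        kclose=lu(1e-3, 1e2),
        kopen=lu(1e-3, 1e2),
        kclose_prime=lu(1e-5, 1e-1),
        kopen_prime=lu(1e-3, 1e1),
        k1_plus=lu(1e-7, 1e-4),
        k1_minus=lu(1e-4, 1e-1),
        k2_plus=lu(1e-7, 1e-4),
        k2_minus=lu(1e-4, 1e-1),
        k3_plus=lu(1e-12, 1e-8),
        k3_minus=lu(1e-5, 1e-2),
    )


def random_reduced_rates(rng: np.random.Generator) -> ReducedRateConstants:
    def lu(lo, hi):
        return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))

    return ReducedRateConstants(
        kf=lu(1e-5, 1e-2),
        kb=lu(1e-4, 1e-1),
        k_plus=lu(1e-5, 1e-2),
        k_minus=lu(1e-5, 1e-2),
        w1=float(rng.uniform(0.001, 1.0)),
        w2=float(rng.uniform(0.001, 1.0)),
    )
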