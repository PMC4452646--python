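import pytest

from modnoise import ReceptorParams


@pytest.fixture(scope="session")
def fast_params() -> ReceptorParams:
    """Fast-switching operating point: k+c0, k- >> gamma (unimodal regime)."""
    return ReceptorParams(k_plus=1.0, c0=20.0, k_minus=100.0, alpha=100.0, gamma=0.1)


@pytest.fixture(scope="session")
def slow_params() -> ReceptorParams:
    """Slow-switching operating point: k+c0, k- << gamma (bimodal CM regime)."""
    return ReceptorParams(
        k_plus=1.0, c0=0.01, k_minus=0.05, alpha=25.0, gamma=1.0, zeta=500
    )


@pytest.fixture(scope="session")
def ramp_params() -> ReceptorParams:
    """Fast-unbinding ramp operating point (k+c0 < k-, BM-favored)."""
    return ReceptorParams(
        k_plus=1.0, c0=1e7, c1=1e5, k_minus=6.7e7, alpha=6.7e7, gamma=1.0
    )
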