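import numpy as np
import pytest

from thermoneutral import ThermalCurveParams, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20170922)


@pytest.fixture(scope="session")
def within_tnz_table():
    """One within-TNZ study realization (26 animals, status-only truth)."""
    return simulate_study(seed=42, within_tnz=True)


@pytest.fixture
def flat_curve():
    """A curve whose plateau covers every tested temperature (pure null)."""
    return ThermalCurveParams(plateau=1.0, lct_c=-50.0, uct_c=100.0,
                              sigma_u=0.0)
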