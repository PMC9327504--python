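import numpy as np
import pytest

from wsisim import QCPolicy, QualityModel, ScannerProfile, load_table1


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture
def poisson_profile():
    return ScannerProfile(name="test", time_model="poisson", mean_scan_s=60.0, load_s=10.0)


@pytest.fixture
def silent_policy():
    """No rescans, no flags, no reviews: the pass-through baseline."""
    return QCPolicy(
        auto_rescan_rate=0.0,
        quality=QualityModel(sigma=0.0, threshold=-np.inf),
        control_rate=0.0,
    )
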