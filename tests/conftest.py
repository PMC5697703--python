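import numpy as np
import pytest

from ampulse.slr import PulseSpec, design_refocusing
from ampulse.root_flip import design_root_flipped


@pytest.fixture(scope="session")
def base_tbp4():
    """Single-band TBP=4 linear-phase refocusing design (pulse, exact pair)."""
    return design_refocusing(PulseSpec(tbp=4))


@pytest.fixture(scope="session")
def base_tbp2():
    return design_refocusing(PulseSpec(tbp=2))


@pytest.fixture(scope="session")
def rootflip_mb4_am():
    """Small AM root-flipped design reused across tests (MB4/TBP4/sep4)."""
    return design_root_flipped(4, 4, 4, am=True, seed=6,
                               ga_population=24, generations=15, stagnation=10)


@pytest.fixture(scope="session")
def rootflip_mb4_unc():
    return design_root_flipped(4, 4, 4, am=False, seed=5,
                               ga_population=24, generations=15, stagnation=10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
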