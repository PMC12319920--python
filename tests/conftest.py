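import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

from dfmri.acquisition import BlockDesign, build_default_scheme, schedule_block
from dfmri.synth import PhantomSpec, RegionSpec, substrate_from_moments


@pytest.fixture(scope="session")
def default_scheme():
    return build_default_scheme(9.5)


@pytest.fixture(scope="session")
def dwi_design():
    return BlockDesign(n_epochs=3, rest_s=28.0, stim_s=28.0, tr=2.0)


@pytest.fixture(scope="session")
def bold_design():
    return BlockDesign(n_epochs=6, rest_s=28.0, stim_s=28.0, tr=1.0)


@pytest.fixture(scope="session")
def dwi_schedule(dwi_design, default_scheme):
    return schedule_block(dwi_design, default_scheme)


@pytest.fixture
def uniform_phantom():
    """Single-region 2x2x1 phantom with gray-matter-like microstructure."""
    sub = substrate_from_moments(0.70, 0.86, 53.8)
    return PhantomSpec(
        labels=np.ones((2, 2, 1), dtype=int),
        regions={1: RegionSpec("gm", rest=sub, stimulus=sub, snr=20.0)},
        s0=100.0,
    )
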