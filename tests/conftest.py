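import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from histotex.synthetic_data import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Reduced-size cohort that still survives all three resolutions."""
    return SyntheticConfig(
        rows=136,
        columns=168,
        n_nuclei=25,
        collagen_strands=12,
        master_seed=7,
    )
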