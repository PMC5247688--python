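import numpy as np
import pytest

from cardiofib.myocyte import MyocyteParams
from cardiofib.fibroblast import FibroblastParams


@pytest.fixture(scope="session")
def mp_default():
    return MyocyteParams()


@pytest.fixture(scope="session")
def fp_default():
    return FibroblastParams()


@pytest.fixture(scope="session")
def relaxed_myocyte():
    """Myocyte state after 10 s unstimulated relaxation (approximate rest)."""
    from cardiofib.myocyte import relax_myocyte

    return relax_myocyte(MyocyteParams(), t_ms=10000.0)


@pytest.fixture(scope="session")
def baseline_last_beat():
    """Last beat of a 10-beat 2 Hz train at x = y = 1 (no EAD expected)."""
    from cardiofib.coupled import pace_unit

    return pace_unit(MyocyteParams(x=1.0, y=1.0), n_beats=10)
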