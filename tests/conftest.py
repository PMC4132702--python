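import numpy as np
import pytest

from mpgkin import fixtures as fx
from mpgkin.fixtures import paper_fixtures


@pytest.fixture(scope="session")
def catalog():
    return paper_fixtures()


@pytest.fixture(scope="session")
def burst_times():
    """0-10 min at 0.25-min steps, the burst-assay sampling grid."""
    return np.arange(0.0, 10.0 + 0.125, 0.25)


@pytest.fixture(scope="session")
def repair_times():
    """Standard in-cell harvest grid, hours."""
    return np.array(fx.REPAIR_TIMES_H)
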