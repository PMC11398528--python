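import logging

import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # pipelines log QC notices; keep test output readable
    logging.getLogger("microquant").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_disk_mask():
    """Two overlapping r=6 disks whose centres are 10 px apart."""
    yy, xx = np.mgrid[:40, :40]
    return (((xx - 15) ** 2 + (yy - 20) ** 2) <= 36) | \
           (((xx - 25) ** 2 + (yy - 20) ** 2) <= 36)
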