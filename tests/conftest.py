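import numpy as np
import pytest

import hippovaso as hv
from hippovaso import phantom as ph
from hippovaso import preprocess as pp

GRID = (48, 48, 48)


@pytest.fixture(scope="session")
def phantom():
    return hv.build_phantom(GRID, seed=0)


@pytest.fixture(scope="session")
def design():
    return hv.make_task_design(order_seed=0)


@pytest.fixture(scope="session")
def params():
    return ph.AcquisitionParams()


@pytest.fixture(scope="session")
def quiet_run(phantom, design, params):
    """Noise-free, drift-free run: demultiplexed, trimmed 2/2, corrected."""
    series = hv.simulate_interleaved(
        phantom, design, params, seed=1, noise_sd=0.0, with_drift=False
    )
    nulled, notnulled = pp.demultiplex(series)
    del series
    nulled = pp.trim(nulled, 2, 2)
    notnulled = pp.trim(notnulled, 2, 2)
    vaso = pp.bold_correct(nulled, notnulled)
    bold = pp.ContrastSeries(
        notnulled.data, "bold", notnulled.timestamp_ms, dict(notnulled.provenance)
    )
    return {"nulled": nulled, "notnulled": notnulled, "vaso": vaso, "bold": bold}


def make_series(data, contrast="nulled", tr_ms=3000.0):
    """Small ContrastSeries helper for unit tests."""
    data = np.asarray(data, dtype=float)
    return pp.ContrastSeries(
        data=data,
        contrast=contrast,
        timestamp_ms=np.arange(data.shape[-1]) * tr_ms,
    )
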