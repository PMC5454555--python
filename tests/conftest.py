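import numpy as np
import pytest

import balancelab as bl


@pytest.fixture(scope="session")
def unit_gains():
    return {d: 1.0 for d in bl.DIRECTIONS}


@pytest.fixture(scope="session")
def noiseless_calibration(unit_gains):
    """Six perfect static recordings from an unbiased sensor."""
    return {
        d: bl.simulate_static(d, gains=unit_gains, noise_sd=0.0, seed=0, device_id="ideal")
        for d in bl.DIRECTIONS
    }


@pytest.fixture(scope="session")
def disk_study(tmp_path_factory):
    """A small simulated study written to disk, loaded back once."""
    out = tmp_path_factory.mktemp("study")
    params = bl.SwayParams(seed=11)
    manifest = bl.simulate_session(out, 2, params, seed=11)
    return manifest, bl.load_study(manifest)


@pytest.fixture(scope="session")
def memory_study():
    """A two-participant study simulated in memory, with its metrics table."""
    params = bl.SwayParams(seed=5)
    sessions, ground_truth = bl.simulate_study(2, params, seed=5)
    factors = {
        dev: bl.derive_correction_factors(recs, device_id=dev)
        for dev, recs in sessions[0].calibrations.items()
    }
    table = bl.session_metrics(sessions, factors, variant="deviation")
    return sessions, ground_truth, factors, table
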