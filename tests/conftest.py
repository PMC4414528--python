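import numpy as np
import pytest

from auxring.model import TransportParams
from auxring.simulate import SimulationConfig, run_ensemble
from auxring.workflows import ensemble_summary_frame

# influx sweep of the periodicity/trend analyses (μM/s)
I_SWEEP = (0.001, 0.1, 10.0, 100.0)
# efflux sweep at high passive influx (D_ca = 50/s), all above the
# patterning threshold
E_SWEEP = (20.0, 50.0, 105.0, 200.0)
N_REPLICATES = 30


@pytest.fixture(scope="session")
def default_params() -> TransportParams:
    return TransportParams()


def _sweep_frames(axis: str, values, base_seed: int, **param_overrides):
    frames = {}
    for v in values:
        params = TransportParams(**param_overrides).with_(**{axis: v})
        cfg = SimulationConfig(params=params, n_replicates=N_REPLICATES,
                               base_seed=base_seed)
        result = run_ensemble(cfg)
        assert not result.failures
        frames[v] = ensemble_summary_frame(result)
    return frames


@pytest.fixture(scope="session")
def i_sweep_frames():
    """30-replicate ensembles along the influx sweep at the default set."""
    return _sweep_frames("I", I_SWEEP, base_seed=100)


@pytest.fixture(scope="session")
def e_sweep_frames():
    """30-replicate ensembles along the efflux sweep at D_ca = 50/s, I = 100."""
    return _sweep_frames("E", E_SWEEP, base_seed=200, D_ca=50.0)


def median_stat(frame, compartment: str, column: str) -> float:
    sub = frame[frame.compartment == compartment]
    return float(np.median(sub[column]))
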