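import numpy as np
import pytest

from xstain.geomgrow import GeometryModel
from xstain.stainpde import KineticParams
from xstain.synthdata import AcquisitionSpec, GroundTruth


@pytest.fixture()
def geom():
    return GeometryModel()


@pytest.fixture()
def flat_geom():
    return GeometryModel(flat=True)


@pytest.fixture()
def kinetics():
    return KineticParams()


@pytest.fixture()
def acq():
    return AcquisitionSpec()


@pytest.fixture()
def quiet_truth():
    """Noise-free, jitter-free, static-surface ground truth."""
    acq = AcquisitionSpec()
    return GroundTruth(growth=None, shifts=np.zeros((acq.n_frames, 2)),
                       noise_sigma=0.0, drift_amplitude=0.0)


@pytest.fixture(autouse=True)
def _quiet_resolution_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="grid spacing .* may under-resolve")
        yield
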