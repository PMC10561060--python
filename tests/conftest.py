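import numpy as np
import pytest

from cheradapt import GroundTruth, MWCParams, TPMParams
from cheradapt.kinetics import AdaptationParams


@pytest.fixture(scope="session")
def tar_params() -> MWCParams:
    """MeAsp/Tar MWC calibration with the Tar-only cluster size."""
    return MWCParams(N=8.7, alpha=-1.875, m0=1.0, Koff=0.0182, Kon=3.0)


@pytest.fixture(scope="session")
def tar_tpm() -> TPMParams:
    """Wild-type Tar tether: 34 residues, fitted translation 10.5 nm."""
    return TPMParams(L_total=12.24, b=0.76, x0=10.5, c=2.0)


@pytest.fixture(scope="session")
def tar_distances():
    """Tar site distances in sequential methylation order, nm."""
    return [6.75, 5.70, 4.65, 3.45]


@pytest.fixture()
def tar_truth() -> GroundTruth:
    return GroundTruth(seed=42)


@pytest.fixture()
def quiet_truth() -> GroundTruth:
    """Noise-free ground truth for exactness checks."""
    return GroundTruth(seed=0, noise_sd=0.0)
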