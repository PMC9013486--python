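import warnings

import numpy as np
import pytest

from c4spectra.c4_model import C4Constants, LeafPhotoParams, NonPhysicalWarning


@pytest.fixture(autouse=True)
def _quiet_nonphysical():
    """Non-physical-state warnings on unused model branches are routine."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonPhysicalWarning)
        yield


@pytest.fixture
def consts() -> C4Constants:
    return C4Constants()


@pytest.fixture
def ref_params() -> LeafPhotoParams:
    """A mid-range sorghum-like leaf parameter set."""
    return LeafPhotoParams(Vcmax=51.0, Vpmax=410.0, Jmax=400.0, Rd=2.0,
                           theta=0.3, PSabs=0.35, gm=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
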