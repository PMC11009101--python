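import numpy as np
import pytest

from minsted_track import EPSF, ScanConfig

# Standard operating point: minimum-FWHM E-PSF (26 nm), circle diameter
# matching the FWHM, 15% update fraction, 14 kHz count rate.
FWHM = 26.0
ALPHA = 0.15
RATE = 14000.0


@pytest.fixture(scope="session")
def epsf() -> EPSF:
    return EPSF.from_fwhm(FWHM)


@pytest.fixture(scope="session")
def scan(epsf) -> ScanConfig:
    return ScanConfig.matched(epsf, rate=RATE, alpha=ALPHA)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
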