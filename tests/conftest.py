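"""Shared fixtures: small LUTs, geometries and rendered scenes."""

import numpy as np
import pytest

from speckleflow.forward_models import OpticalProperties
from speckleflow.lut_engine import build_lut
from speckleflow.srdrs import ProbeGeometry


@pytest.fixture(scope="session")
def default_lut():
    """Full-range LUT on the standard rho grid (built once per session)."""
    return build_lut()


@pytest.fixture(scope="session")
def small_lut():
    """Coarse LUT for fast structural tests."""
    return build_lut(
        mua_grid=np.linspace(0.0, 0.4, 17),
        musp_grid=np.linspace(0.3, 3.5, 17),
        rho_grid=np.linspace(3.0, 10.0, 29),
    )


@pytest.fixture()
def geometry():
    """Probe geometry matching the default synthetic frames (rho <= 8 mm)."""
    return ProbeGeometry(source_px=(128.0, 28.0), pixel_pitch=0.05,
                         rho_min=3.0, rho_max=8.0, bin_width=0.1)


@pytest.fixture()
def tissue_props():
    return OpticalProperties(mua=0.016, musp=1.0, n=1.4, wavelength=850.0)
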