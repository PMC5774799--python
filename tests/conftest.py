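"""Shared fixtures: grids, acquisition settings and small demo phantoms.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from boldpert import (
    AcquisitionParams,
    HRFParams,
    SusceptibilityVolume,
    VoxelGrid,
    canonical_hrf,
    chi_to_field,
    effective_regressor,
    make_background_chi,
    make_task_paradigm,
)
from boldpert.phantom import BlobSpec


@pytest.fixture(scope="session")
def grid32() -> VoxelGrid:
    return VoxelGrid((32, 32, 32))


@pytest.fixture(scope="session")
def grid64() -> VoxelGrid:
    return VoxelGrid((64, 64, 64))


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    """7T protocol (B0 = 7 T, TE = 29 ms) without supersampling."""
    return AcquisitionParams(supersample=1)


@pytest.fixture(scope="session")
def regressor_7t():
    """Effective regressor of the 50-volume block design at TR = 3 s."""
    paradigm = make_task_paradigm([("ON", 5), ("OFF", 5)] * 5, tr_s=3.0)
    return effective_regressor(paradigm, canonical_hrf(HRFParams(), tr_s=3.0))


@pytest.fixture(scope="session")
def unit_sphere_32(grid32, acq):
    """1-ppm sphere (radius 5 mm) and its forward field on a 32^3 grid."""
    chi = make_background_chi(
        grid32,
        [BlobSpec((0.0, 0.0, 0.0), 5.0, 1.0)],
        envelope_semiaxes_mm=(15.0, 15.0, 15.0),
    )
    return chi, chi_to_field(chi, acq)


@pytest.fixture(scope="session")
def unit_sphere_64(grid64, acq):
    """1-ppm sphere (radius 6 mm) and its forward field on a 64^3 grid."""
    chi = make_background_chi(
        grid64,
        [BlobSpec((0.0, 0.0, 0.0), 6.0, 1.0)],
        envelope_semiaxes_mm=(30.0, 30.0, 30.0),
    )
    return chi, chi_to_field(chi, acq)
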