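"""Shared fixtures: desk-scale phantom grids and simulated acquisitions.

Heavy objects are session-scoped so the full suite voxelizes and simulates
each configuration once.
"""

from __future__ import annotations

import numpy as np
import pytest

import ra224spect as r
from ra224spect.simulate import AcquisitionProtocol

DESK_SHAPE = (64, 64, 40)
DESK_SPACING = 4.8
DESK_VIEWS = 24


@pytest.fixture(scope="session")
def phantom30():
    return r.PhantomSpec(sphere_concentrations=(30.0,) * 6)


@pytest.fixture(scope="session")
def desk_volumes(phantom30):
    """Activity and mu volumes of the 30-kBq/mL phantom on the desk grid."""
    return r.voxelize(
        phantom30, DESK_SPACING, r.MU_WATER_PER_CM[240],
        shape=DESK_SHAPE, subsample=2,
    )


@pytest.fixture(scope="session")
def me240_protocol():
    system = r.preset_systems()["ME240"]
    return AcquisitionProtocol(
        n_views=DESK_VIEWS, t_view=30.0, matrix=DESK_SHAPE[0],
        bin_size=DESK_SPACING, windows=system.windows,
    )


@pytest.fixture(scope="session")
def me240_projections(desk_volumes, me240_protocol):
    act, mu = desk_volumes
    system = r.preset_systems()["ME240"]
    return r.simulate_acquisition(act, mu, system, me240_protocol, seed=42)


@pytest.fixture(scope="session")
def background_mask(phantom30):
    bg = r.background_voi(phantom30, DESK_SPACING, 40.2, 26.8, shape=DESK_SHAPE)
    return np.asarray(bg.values, dtype=bool)
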