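"""Shared fixtures.

Simulation-backed fixtures are session-scoped: several tests interrogate
the same records (water references, homogeneous slabs), and the solver
is deterministic, so reuse is safe and keeps the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from porebone import (
    MaterialTable,
    SimGrid,
    SourceConfig,
    run_simulation,
    time_settings,
    water_reference,
)
from porebone.materials import LABEL_CORTICAL, LABEL_MARROW
from porebone.solver.medium import assign_materials, homogeneous_slab_labels

C_CORTICAL = 3514.0


@pytest.fixture(scope="session")
def mat() -> MaterialTable:
    return MaterialTable()


@pytest.fixture(scope="session")
def grid1d() -> SimGrid:
    return SimGrid(dims=(152,), spacing=0.05)


@pytest.fixture(scope="session")
def grid2d_small() -> SimGrid:
    return SimGrid(dims=(32, 152), spacing=0.05)


@pytest.fixture(scope="session")
def src650() -> SourceConfig:
    return SourceConfig(frequency=650e3)


@pytest.fixture(scope="session")
def ts650_1d(grid1d):
    return time_settings(650e3, grid1d, c_max=C_CORTICAL)


@pytest.fixture(scope="session")
def water650_1d(src650, ts650_1d, grid1d, mat):
    return water_reference(src650, ts650_1d, grid1d, mat)


@pytest.fixture(scope="session")
def cortical650_1d(src650, ts650_1d, grid1d, mat):
    medium = assign_materials(homogeneous_slab_labels(grid1d, LABEL_CORTICAL), mat, False, 650e3)
    return run_simulation(medium, src650, ts650_1d, grid1d)


@pytest.fixture(scope="session")
def marrow650_1d(src650, ts650_1d, grid1d, mat):
    medium = assign_materials(homogeneous_slab_labels(grid1d, LABEL_MARROW), mat, False, 650e3)
    return run_simulation(medium, src650, ts650_1d, grid1d)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
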