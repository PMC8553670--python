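"""Shared fixtures: geometries are expensive, so build them once per session."""

import numpy as np
import pytest

from yaptaz3d import geometry as geo
from yaptaz3d.model_core import ActivationProtocol, ParameterSet


#: coarse grid used for fast solver tests (resolves the nucleus and band)
COARSE_GRID = (40, 17, 13)
#: very small grid for sweep plumbing tests
TINY_GRID = (24, 11, 9)


@pytest.fixture(scope="session")
def shape16():
    return geo.build_cell_shape(16.0)


@pytest.fixture(scope="session")
def geom_default(shape16):
    return geo.voxelize(shape16, geo.DEFAULT_GRID)


@pytest.fixture(scope="session")
def geom_coarse(shape16):
    return geo.voxelize(shape16, COARSE_GRID)


@pytest.fixture(scope="session")
def geom_tiny(shape16):
    return geo.voxelize(shape16, TINY_GRID)


@pytest.fixture()
def params():
    return ParameterSet()


@pytest.fixture()
def protocol():
    return ActivationProtocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210910)
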