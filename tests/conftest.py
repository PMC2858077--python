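import numpy as np
import pytest

import bicoid2d as b


@pytest.fixture(scope="session")
def main_config():
    return b.preset("main")


@pytest.fixture(scope="session")
def main_geom(main_config):
    return b.build_geometry(main_config.L, main_config.aspect, main_config.params.dx)


@pytest.fixture(scope="session")
def main_run(main_config):
    """One full wild-type simulation, shared by the analysis-level tests."""
    return b.run(main_config)


@pytest.fixture()
def strip_geom():
    """Homogeneous 1-D strip (single row) for closed-form diffusion checks."""
    dx = 5.0
    nx = 120
    xc = (np.arange(nx) + 0.5) * dx
    yc = np.array([0.0])
    mask = np.ones((1, nx), dtype=bool)
    return b.EmbryoGeometry(L=nx * dx, aspect=1.0, dx=dx, xc=xc, yc=yc, mask=mask)
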