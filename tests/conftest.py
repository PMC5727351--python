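import numpy as np
import pytest

from wormstim import (
    build_body_mesh,
    build_default_registry,
    pose_worm,
    reference_state,
)
from wormstim.fixtures import make_fixtures


@pytest.fixture(scope="session")
def mesh():
    return build_body_mesh()


@pytest.fixture(scope="session")
def registry(mesh):
    return build_default_registry(mesh=mesh)


@pytest.fixture(scope="session")
def straight_state(mesh, registry):
    """Straight reference pose: nose at the origin, heading along +x."""
    return pose_worm(mesh, registry, reference_state())


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("assays")
    make_fixtures(str(d))
    return d


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
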