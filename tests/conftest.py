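"""Shared fixtures: default geometry, fibre field, infarct maps and the
healthy/MI forward solutions reused across test modules."""

import numpy as np
import pytest

from lvmech import (ActiveConfig, PassiveParams, build_geometry, build_infarct,
                    generate_fibers, healthy_infarct, solve_diastole,
                    solve_systole)

try:
    from hypothesis import settings
    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def mesh():
    return build_geometry()


@pytest.fixture(scope="session")
def fibers(mesh):
    return generate_fibers(mesh)


@pytest.fixture(scope="session")
def healthy_map(mesh):
    return healthy_infarct(mesh)


@pytest.fixture(scope="session")
def mi_map(mesh):
    return build_infarct(mesh)


@pytest.fixture(scope="session")
def p_healthy():
    return PassiveParams.healthy()


@pytest.fixture(scope="session")
def p_mi():
    return PassiveParams.mi_remote()


@pytest.fixture(scope="session")
def ed_healthy(mesh, fibers, healthy_map, p_healthy):
    return solve_diastole(mesh, fibers, healthy_map, p_healthy, 8.0)


@pytest.fixture(scope="session")
def es_healthy(mesh, fibers, healthy_map, p_healthy, ed_healthy):
    return solve_systole(mesh, fibers, healthy_map, p_healthy, ActiveConfig(),
                         144.6, ed_healthy)


@pytest.fixture(scope="session")
def ed_mi(mesh, fibers, mi_map, p_mi):
    return solve_diastole(mesh, fibers, mi_map, p_mi, 16.0)


@pytest.fixture(scope="session")
def es_mi(mesh, fibers, mi_map, p_mi, ed_mi):
    return solve_systole(mesh, fibers, mi_map, p_mi, ActiveConfig(T_req=156.0),
                         118.6, ed_mi)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
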