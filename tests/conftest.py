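import numpy as np
import pytest

from mechangio import SimConfig, generate_cube_mesh, build_initial_network


@pytest.fixture(scope="session")
def small_mesh():
    """Uniform 4³ cube, 2 mm edge, no tumour."""
    return generate_cube_mesh(2.0, 4, 0.4)


@pytest.fixture(scope="session")
def tumour_mesh():
    """Uniform 5³ cube, 5 mm edge, 1 mm centred tumour (odd n → the central
    element holds the tumour)."""
    return generate_cube_mesh(5.0, 5, 1.0)


@pytest.fixture(scope="session")
def lattice_network(tumour_mesh):
    return build_initial_network(tumour_mesh, spacing=1.0, radius_um=30.0,
                                 thickness_um=3.0, pore_um=0.005)


def coarse_config(**overrides) -> SimConfig:
    """The reduced-scale reference scenario used by the emergent-behaviour
    tests: 6 mm cube, centre-refined grid (finest edge 0.4 mm), 1 mm
    tumour, otherwise the study defaults."""
    cfg = SimConfig()
    cfg.mesh.edge_length_mm = 6.0
    cfg.mesh.h_centre_mm = 0.4
    for key, val in overrides.items():
        obj = cfg
        *path, last = key.split(".")
        for part in path:
            obj = getattr(obj, part)
        setattr(obj, last, val)
    return cfg


def make_network(pos, segments, **kw):
    """Hand-built small network helper used across test modules."""
    from mechangio.network import VascularNetwork
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    defaults = dict(
        pos=pos, birth_time=np.zeros(n), is_tip=np.zeros(n, bool),
        is_inlet=np.zeros(n, bool), is_outlet=np.zeros(n, bool),
        frozen=np.zeros(n, bool), radius_um=np.full(n, 30.0),
        radius_base_um=np.full(n, 30.0), thickness_um=np.full(n, 3.0),
        pore_um=np.full(n, 0.005), state=np.zeros(n, np.int8),
        host_elem=np.full(n, -1), local=np.zeros((n, 3)),
        direction=np.tile([1.0, 0, 0], (n, 1)),
        segments=np.asarray(segments, dtype=int).reshape(-1, 2),
        rest_length=None)
    defaults.update(kw)
    net = VascularNetwork(**defaults)
    if net.rest_length is None:
        net.rest_length = net.segment_lengths()
    return net
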