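import numpy as np
import pytest

from gtam.gta_core import EncoderConfig, GTAEncoder2D, GTAEncoder3D
from gtam.synthfix import FixtureSpec, make_fixture_set


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale encoder: small widths so brute-force oracles stay cheap."""
    return EncoderConfig(d_h=16, d_z=16, n_triangle_blocks=1, n_heads=2,
                         d_hidden=16)


@pytest.fixture(scope="session")
def fixtures():
    """Eight paired toy molecules (bond type determines bond length)."""
    return make_fixture_set(FixtureSpec(n_molecules=8, seed=11))


@pytest.fixture(scope="session")
def fixtures_large():
    return make_fixture_set(FixtureSpec(n_molecules=20, seed=23))


@pytest.fixture(scope="session")
def enc2d(small_config):
    return GTAEncoder2D(small_config, seed=0)


@pytest.fixture(scope="session")
def enc3d(small_config):
    return GTAEncoder3D(small_config, seed=0)


def random_graph2d(n, rng, p_edge=0.5):
    """Random connected molecular-style graph for oracle comparisons."""
    from gtam.molio import Graph2D

    src, dst, et = [], [], []
    # random spanning tree keeps the graph connected
    for v in range(1, n):
        u = int(rng.integers(0, v))
        t = int(rng.integers(0, 4))
        src += [u, v]; dst += [v, u]; et += [t, t]
    for u in range(n):
        for v in range(u + 1, n):
            if (u, v) not in {(min(a, b), max(a, b)) for a, b in zip(src, dst)}:
                if rng.random() < p_edge - 0.5 + 0.2:
                    t = int(rng.integers(0, 4))
                    src += [u, v]; dst += [v, u]; et += [t, t]
    return Graph2D(
        element_idx=rng.integers(0, 4, size=n),
        formal_charge=np.zeros(n, dtype=int),
        is_aromatic_atom=np.zeros(n, dtype=bool),
        edge_index=np.array([src, dst]),
        edge_type=np.array(et),
    )
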