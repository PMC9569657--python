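import numpy as np
import pytest

from combflow import ModelParams, ShearBox, build_comb, init_polymer_configuration


@pytest.fixture(scope="session")
def model_params():
    return ModelParams()


@pytest.fixture(scope="session")
def comb_20_20():
    return build_comb(20, 20, 20)


@pytest.fixture()
def random_chain(model_params):
    """A grown 20-bead chain in a roomy box, with its box."""
    topo = build_comb(20, 0, 0)
    box = ShearBox(50.0)
    pos, vel = init_polymer_configuration(topo, box, seed=7, params=model_params)
    return topo, box, pos, vel


def brute_force_gyration(positions):
    """Double-loop oracle for the gyration tensor."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    cm = [sum(positions[i][a] for i in range(n)) / n for a in range(3)]
    G = np.zeros((3, 3))
    for i in range(n):
        for a in range(3):
            for b in range(3):
                G[a, b] += (positions[i][a] - cm[a]) * (positions[i][b] - cm[b])
    return G / n
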