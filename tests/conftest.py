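import numpy as np
import pytest

import refratio as rr


@pytest.fixture(scope="session")
def default_params() -> rr.LocalModelParams:
    return rr.LocalModelParams.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ubiquitin() -> rr.Sequence:
    return rr.UBIQUITIN_1UBQ


@pytest.fixture(scope="session")
def protein_g() -> rr.Sequence:
    return rr.PROTEIN_G_2GB1


def make_two_state_params(p_stay: float = 0.5, spread: float = 10.0):
    """Small two-state model (helix/strand) used by several tests."""
    states = [
        rr.BasinState(id=0, label="H", mean_phi=-63.0, mean_psi=-43.0,
                      spread=spread),
        rr.BasinState(id=1, label="E", mean_phi=-120.0, mean_psi=130.0,
                      spread=spread),
    ]
    t = np.array([[p_stay, 1 - p_stay], [1 - p_stay, p_stay]])
    return rr.LocalModelParams(states=states, initial=np.array([0.5, 0.5]),
                               transition={"generic": t})


@pytest.fixture()
def two_state_params():
    return make_two_state_params()


@pytest.fixture(scope="session")
def toy_system() -> rr.ToySystem:
    transition = np.array([
        [0.6, 0.2, 0.2],
        [0.2, 0.6, 0.2],
        [0.2, 0.2, 0.6],
    ])
    g = (np.arange(8) + 1.0) ** 2
    return rr.ToySystem(L=8, transition=transition, target=g / g.sum())
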