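import numpy as np
import pytest

from gfsm.core import ElectronicStateSet


def random_hermitian_system(rng, n_states=None, min_denominator=1e-3):
    """Random Hermitian few-state system with all energy denominators
    bounded away from the two-photon resonance for every choice of final
    state (the physical precondition of the undamped theory)."""
    if n_states is None:
        n_states = int(rng.integers(2, 7))
    while True:
        energies = np.concatenate(
            [[0.0], np.sort(rng.uniform(0.05, 0.2, size=n_states - 1))]
        )
        ok = all(
            np.min(np.abs(energies - energies[J] / 2.0)) > min_denominator
            for J in range(1, n_states)
        )
        if ok:
            break
    mu = rng.normal(size=(n_states, n_states, 3))
    mu = (mu + mu.transpose(1, 0, 2)) / 2.0
    return ElectronicStateSet(energies, mu)


@pytest.fixture
def rng():
    return np.random.default_rng(20210323)


@pytest.fixture
def two_level_system():
    """The hand-evaluated worked example: E1 = 0.1 au, mu01 = z, mu11 = 2z,
    no ground-state dipole."""
    return ElectronicStateSet.from_pairs(
        [0.0, 0.1], {(0, 1): (0, 0, 1), (1, 1): (0, 0, 2)}
    )
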