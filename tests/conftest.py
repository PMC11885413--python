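import itertools

import numpy as np
import pytest

from underdrive import EcologicalRates, SimulationProtocol
from underdrive.genetics import GENOTYPES, gamete_distribution


@pytest.fixture(scope="session")
def rates():
    return EcologicalRates()


@pytest.fixture(scope="session")
def protocol():
    return SimulationProtocol()


@pytest.fixture(scope="session")
def fast_protocol():
    """Shorter horizon for tests where full convergence is not the point."""
    return SimulationProtocol(horizon=100)


def offspring_by_mating_pairs(densities: np.ndarray) -> np.ndarray:
    """Brute-force offspring densities over all 81 ordered mating pairs.

    Independent oracle for the gamete-pool construction: each ordered
    parental pair (i, j) contributes with weight N_i * N_j / N^2, and its
    offspring distribution is the outer product of the parents' gamete
    distributions mapped onto genotypes.
    """
    n = np.asarray(densities, dtype=float)
    total = n.sum()
    if total == 0:
        return np.zeros(9)
    p = n / total  # normalise first: total**2 can underflow for tiny inputs
    out = np.zeros(9)
    for gi, gj in itertools.product(GENOTYPES, GENOTYPES):
        w = p[gi.index] * p[gj.index]
        if w == 0:
            continue
        di, dj = gamete_distribution(gi), gamete_distribution(gj)
        for a in range(4):
            for b in range(4):
                ca = (a < 2) + (b < 2)  # gametes 0,1 carry A
                cb = (a % 2 == 0) + (b % 2 == 0)  # gametes 0,2 carry B
                out[(2 - ca) * 3 + (2 - cb)] += w * di[a] * dj[b]
    return total * out
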