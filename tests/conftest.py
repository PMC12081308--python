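import itertools

import numpy as np
import pytest

from trophoflux.chem import ISOTOPE_ABUNDANCES, ElementalFormula
from trophoflux.synthio import MsConfig, SimConfig


def brute_force_envelope(formula: ElementalFormula, n: int) -> np.ndarray:
    """Independent oracle: enumerate every isotope assignment of every atom.

    Exponential in the atom count, so only usable for molecules with few
    polyisotopic atoms; exact to floating-point for those.
    """
    atoms = []
    for el, count in formula.counts.items():
        dist = ISOTOPE_ABUNDANCES[el]
        atoms.extend([dist] * count)
    probs = np.zeros(n + 64)
    for combo in itertools.product(*[range(len(d)) for d in atoms]):
        p = 1.0
        for dist, k in zip(atoms, combo):
            p *= dist[k]
        probs[sum(combo)] += p
    return probs[:n]


@pytest.fixture
def noise_free_ms() -> SimConfig:
    return SimConfig(
        seed=11, ms=MsConfig(noise_cv=0.0, spikein_cv=0.0, label_fractions=0.25)
    )


@pytest.fixture
def default_sim() -> SimConfig:
    return SimConfig(seed=7)
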