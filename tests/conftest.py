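import numpy as np
import pytest

from bqte import TrialData


def random_trial(rng: np.random.Generator, n0: int | None = None,
                 n1: int | None = None, lattice: float | None = 0.5) -> TrialData:
    """Small random duration trial; outcomes on a half-day lattice by default."""
    n0 = n0 or int(rng.integers(3, 12))
    n1 = n1 or int(rng.integers(3, 12))
    c = rng.gamma(4.0, 2.0, size=n0)
    t = rng.gamma(4.0, 1.6, size=n1)
    if lattice:
        c = np.round(c / lattice) * lattice
        t = np.round(t / lattice) * lattice
    return TrialData.from_arrays(c, t)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def shift_trial() -> TrialData:
    """Equal-size trial where treatment is exactly control minus 3 days."""
    control = np.array([4.0, 5.5, 7.0, 8.0, 9.5, 11.0, 12.5, 15.0, 17.0, 21.0])
    return TrialData.from_arrays(control, control - 3.0)
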