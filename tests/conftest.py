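import numpy as np
import pytest

from peatdom.chem import Formula
from peatdom.synthetic import HabitatProfile, generate_compound_library


@pytest.fixture(scope="session")
def fen_profile() -> HabitatProfile:
    return HabitatProfile("fen", mean_oc=0.55, mean_hc=1.35, n_compounds=200, lability_index=0.7)


@pytest.fixture(scope="session")
def small_library(fen_profile) -> list[Formula]:
    """200 rule-valid formulas, sorted by mass, shared across tests."""
    return sorted(generate_compound_library(fen_profile, seed=1), key=lambda f: f.mass)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_valid_formula(rng: np.random.Generator) -> Formula:
    """A random rule-bounded CHO(N) formula for differential/property checks."""
    c = int(rng.integers(5, 40))
    h = 2 * int(rng.integers(max(1, int(0.2 * c)), c + 1))
    o = int(rng.integers(0, int(1.2 * c) + 1))
    return Formula(c=c, h=h, o=o)
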