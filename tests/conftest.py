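import numpy as np
import pytest

from xhap import (
    FamilySpec,
    default_panel,
    draw_fathers,
    draw_mother,
    simulate_adults,
    simulate_family,
    study_scenario,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def adults():
    """One simulated field collection (14 localities x 30 adults)."""
    return simulate_adults(study_scenario(seed=11))


@pytest.fixture(scope="session")
def family_with_truth(panel):
    """One simulated polyandrous family (8 distinct fathers, 200 larvae)."""
    rng = np.random.default_rng(21)
    mother = draw_mother(panel, rng, {"49": 2, "61": 4})
    fathers = draw_fathers(panel, 8, rng)
    fam = simulate_family(
        FamilySpec(n_fathers=8, n_larvae=200), mother, fathers, panel, rng=rng
    )
    return fam, mother, fathers
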