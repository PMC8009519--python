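
import pytest

from hpfsurf import (SystemSpec, build_system, default_adoh_forcefield,
                     make_brownian_trajectory, make_planted_clusters)


@pytest.fixture(scope="session")
def ff_water():
    return default_adoh_forcefield("W")


@pytest.fixture(scope="session")
def ff_cyclohexane_charged():
    return default_adoh_forcefield("C", charged_tails=True)


@pytest.fixture(scope="session")
def small_water_system(ff_water):
    """50 mM ADOH in a 6 nm water box: 7 surfactant molecules, ~1.8k beads."""
    spec = SystemSpec(concentration=50, box_edge=6.0, solvent="W", seed=7)
    return build_system(spec, ff_water)


@pytest.fixture(scope="session")
def planted_census():
    """The 7/2/2/1/1 molecule census with its ground-truth partition."""
    state, truth = make_planted_clusters([7, 2, 2, 1, 1], 20.0, 0.4, seed=1)
    return state, truth


@pytest.fixture(scope="session")
def brownian_half():
    """500 walkers, D = 0.5 nm^2/ps, 2000 frames of 0.1 ps."""
    return make_brownian_trajectory(500, 0.5, 2000, 0.1, 50.0, seed=3)
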