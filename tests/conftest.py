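import numpy as np
import pytest

from profdesign.energy import DesignConfig
from profdesign.features import PropensityPredictor
from profdesign.fixtures import FamilySpec, make_family, make_ideal_structure
from profdesign.profile import profile_from_library
from profdesign.structio import assign_features


@pytest.fixture(scope="session")
def helix40():
    return make_ideal_structure("helix_bundle", 40, seed=0)


@pytest.fixture(scope="session")
def helix40_feats(helix40):
    return assign_features(helix40)


@pytest.fixture(scope="session")
def family15():
    """Scaffold + 15 jittered/mutated homologs + generating distribution."""
    return make_family(FamilySpec(n_members=15, length=40, seed=0))


@pytest.fixture(scope="session")
def family_profile(family15):
    scaffold, members, _ = family15
    prof, threshold = profile_from_library(scaffold, members)
    return prof, threshold


@pytest.fixture(scope="session")
def propensity():
    return PropensityPredictor(window=15)


@pytest.fixture()
def small_config():
    """Scaled-down search settings for fast unit tests."""
    return DesignConfig(n_traj=2, n_sweeps=200, burn_in=50,
                        n_baseline=200, seed=1)
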