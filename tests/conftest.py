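import numpy as np
import pytest

import abmlink as al
from abmlink.grids import GridSpec


@pytest.fixture(scope="session")
def preset_2d():
    return al.melanophore_preset(2)


@pytest.fixture(scope="session")
def preset_1d():
    return al.melanophore_preset(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def solution_as_ensemble(sol):
    """Wrap a continuum solution as EA data for parameter-recovery tests."""
    return al.EnsembleDensity(
        fields=sol.fields,
        n_sim=1,
        count_mean=sol.mass,
        count_std=np.zeros_like(sol.mass),
    )


@pytest.fixture(scope="session")
def small_grid_2d(preset_2d):
    _, _, _, domain = preset_2d
    return GridSpec.regular(domain, 48)
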