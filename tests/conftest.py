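"""Shared fixtures: one phantom spectrum image reused across the suite.

The reference phantom is the largest quantified core of the study
conditions (23.6 nm at 3.385 Fe/nm^3, ~23,297 atoms) sampled at
0.5 nm/px with the default beam (I0 = 1e8 counts/px, 0.25 eV/channel).
Cubes are generated once per session; quantification results likewise.
"""

import numpy as np
import pytest

from encapquant.eels import QuantConfig, quantify_map
from encapquant.synthetic import BeamSpec, PhantomSpec, make_eels_cube, project_sphere

GRID = (71, 71)
POISSON_SEED = 20260929


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()  # 23.6 nm, 3.385 atoms/nm^3, 0.5 nm/px


@pytest.fixture(scope="session")
def phantom_truth(phantom_spec):
    return project_sphere(phantom_spec, GRID)


@pytest.fixture(scope="session")
def truth_total(phantom_truth, phantom_spec):
    return float(phantom_truth.sum() * phantom_spec.pixel_size_nm**2)


@pytest.fixture(scope="session")
def cube_noise_free(phantom_truth, phantom_spec):
    return make_eels_cube(
        phantom_truth, BeamSpec(noise="none"), phantom_spec.pixel_size_nm, seed=0
    )


@pytest.fixture(scope="session")
def cube_poisson(phantom_truth, phantom_spec):
    return make_eels_cube(
        phantom_truth, BeamSpec(), phantom_spec.pixel_size_nm, seed=POISSON_SEED
    )


@pytest.fixture(scope="session")
def dmap_noise_free(cube_noise_free):
    return quantify_map(cube_noise_free, QuantConfig())


@pytest.fixture(scope="session")
def dmap_poisson(cube_poisson):
    return quantify_map(cube_poisson, QuantConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
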