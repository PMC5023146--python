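"""Shared fixtures: synthetic geometries, materials, cohort tables."""

import numpy as np
import pytest

from v2g import constitutive as cst
from v2g import data, synthetic
from v2g.forward_model import PressureSchedule, to_equivalent_chamber


@pytest.fixture(scope="session")
def sphere_stack():
    """Noise-free spherical stack (R = 3 cm, wall 0.4 cm, 50 slices)."""
    spec = synthetic.SyntheticVentricleSpec(
        semi_axes=(3.0, 3.0, 3.0), wall_thickness=0.4, n_slices=50,
        truncation=0.98, seed=0)
    return synthetic.generate_ventricle(spec)


@pytest.fixture(scope="session")
def ellipsoid_stack():
    """Default synthetic ventricle (ellipsoidal, 12 slices)."""
    return synthetic.generate_ventricle(synthetic.SyntheticVentricleSpec(seed=0))


@pytest.fixture(scope="session")
def dia_material():
    return cst.DEFAULT_MATERIALS["ventricle_diastole"]


@pytest.fixture(scope="session")
def sys_material():
    return cst.DEFAULT_MATERIALS["ventricle_systole"]


@pytest.fixture(scope="session")
def schedule():
    return PressureSchedule()


@pytest.fixture(scope="session")
def ellipsoid_chamber(ellipsoid_stack):
    return to_equivalent_chamber(ellipsoid_stack)


@pytest.fixture(scope="session")
def predictor_matrix():
    return data.predictor_matrix()


@pytest.fixture(scope="session")
def fitted_patient(ellipsoid_stack):
    """Calibrated 2G model on the default synthetic ventricle."""
    from v2g.geometry import stack_volume
    from v2g.model import TwoGeometryModel

    v_min = stack_volume(ellipsoid_stack, "inner")
    model = TwoGeometryModel(ellipsoid_stack, v_max=1.8 * v_min)
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
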