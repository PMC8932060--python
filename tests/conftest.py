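import numpy as np
import pytest

from pelvisynth.phantom import PhantomParams, generate_cohort
from pelvisynth.registration import RegistrationSettings
from pelvisynth.volumes import ImageVolume, MaskVolume, Modality


@pytest.fixture(scope="session")
def small_params():
    """Compact phantom for module-level tests: anatomy scaled to fit the
    48x48x32 @ 2 mm grid (96x96x64 mm extent)."""
    return PhantomParams(
        grid_shape=(48, 48, 32),
        spacing=(2.0, 2.0, 2.0),
        seed=7,
        **SMALL_ANATOMY,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params, n=3, seed=7)


@pytest.fixture(scope="session")
def small_case(small_cohort):
    return small_cohort.cases[0]


@pytest.fixture(scope="session")
def fast_reg_settings():
    """Reduced iteration caps: enough for the small phantom grids."""
    return RegistrationSettings(
        rigid_iterations=60,
        demons_iterations_per_level=(25, 20, 15),
        bspline_iterations=10,
    )


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                modality=Modality.CT):
    return ImageVolume(np.asarray(values, dtype=float), spacing, origin,
                       np.eye(3), modality)


def make_mask(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return MaskVolume(np.asarray(values, dtype=np.uint8), spacing, origin, np.eye(3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


SMALL_ANATOMY = dict(
    body_axes_range=((30.0, 36.0), (22.0, 27.0)),
    bone_radius_range=(5.0, 7.0),
    bladder_axes_range=(8.0, 11.0),
    gas_pocket_radius_range=(3.0, 5.0),
)
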