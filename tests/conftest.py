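import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from airtrapcad.phantom import PhantomSpec, generate_phantom_pair

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A coarse, fast phantom used by plumbing tests: same anatomy class as
    the default spec (torso, two lungs, bifurcating trachea) at half the
    grid size."""
    kwargs = dict(
        shape=(48, 96, 96),
        spacing=(3.0, 1.0, 1.0),
        body_semiaxes_mm=(37.0, 45.0),
        lung_semiaxes_mm=(60.0, 26.0, 13.0),
        lung_center_offset_mm=26.0,
        lung_center_slice=24,
        trachea_radius_mm=6.0,
        bronchus_radius_mm=4.5,
        bronchus_offset_mm=7.0,
        bifurcation_slice=20,
        bronchus_extent_slices=10,
        seed=11,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_pair():
    """Phantom pair with a known isotropic expiratory shrink of 0.85."""
    spec = small_phantom_spec(s_xy=0.85, s_z=0.85)
    return (spec,) + generate_phantom_pair(spec)


def dice(mask_a, mask_b) -> float:
    a = np.asarray(mask_a.voxels, dtype=bool)
    b = np.asarray(mask_b.voxels, dtype=bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
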