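import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from dbsfuse.phantom import PhantomSpec, generate_phantom_pair  # noqa: E402
from dbsfuse.transforms import RigidTransform  # noqa: E402

# Coarser grids with the same physical FOVs as the default phantom; keeps
# per-test generation well under a second.
SMALL_SPEC = PhantomSpec(
    fine_shape=(64, 64, 64),
    fine_spacing=(0.8, 0.8, 0.8),
    coarse_shape=(48, 48, 48),
    coarse_spacing=(2.0, 2.0, 2.0),
    seed=11,
)


def random_rigid(
    rng: np.random.Generator,
    max_angle_rad: float = np.pi * 0.9,
    max_translation_mm: float = 20.0,
    center=None,
) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = max_angle_rad * rng.uniform()
    versor = np.concatenate([[np.cos(angle / 2)], np.sin(angle / 2) * axis])
    translation = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    c = rng.uniform(-10, 10, size=3) if center is None else np.asarray(center, dtype=float)
    return RigidTransform(versor=versor, translation=translation, center=c)


@pytest.fixture(scope="session")
def rigid_factory():
    return random_rigid


@pytest.fixture(scope="session")
def small_pair():
    return generate_phantom_pair(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_pair():
    return generate_phantom_pair(PhantomSpec(seed=5))
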