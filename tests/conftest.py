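import math

import numpy as np
import pytest

from ellipatch import EllipsoidPatchSpec, PhantomSpec, synthetic_shoulder_volume
from ellipatch.samplers import build_phi_inverse


@pytest.fixture(scope="session")
def sphere_hemisphere():
    """Full upper half of the unit sphere."""
    return EllipsoidPatchSpec(1, 1, 1, 1.0, -1.0, 1.0, -1.0)


@pytest.fixture(scope="session")
def sphere_octant():
    """Positive octant of the unit sphere."""
    return EllipsoidPatchSpec(1, 1, 1, 1.0, 0.0, 1.0, 0.0)


@pytest.fixture(scope="session")
def revolution_patch():
    """Prolate ellipsoid of revolution a1=2, a2=a3=1, full upper half."""
    return EllipsoidPatchSpec(2, 1, 1, 1.0, -1.0, 2.0, -2.0)


@pytest.fixture(scope="session")
def triaxial_patch():
    """General triaxial ellipsoid patch, away from the equator singularity."""
    return EllipsoidPatchSpec(3, 2, 1, 0.9, -0.9, 2.7, -2.7)


@pytest.fixture(scope="session")
def phi_inverse_200():
    return build_phi_inverse(200)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: exact region intensities."""
    return PhantomSpec(noise_sigma=0.0), synthetic_shoulder_volume(
        PhantomSpec(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sigma=5.0, seed=7)
    return spec, synthetic_shoulder_volume(spec)


def random_interior_y(spec, n, seed, margin=0.05):
    """Random points in D_g shrunk by a relative margin (quadrature/FD helpers)."""
    rng = np.random.default_rng(seed)
    lo1, hi1 = spec.y1_bounds
    lo2, hi2 = spec.y2_bounds
    w1, w2 = hi1 - lo1, hi2 - lo2
    y1 = rng.uniform(lo1 + margin * w1, hi1 - margin * w1, n)
    y2 = rng.uniform(lo2 + margin * w2, hi2 - margin * w2, n)
    return y1, y2
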