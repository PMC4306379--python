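"""Synthetic inputs: a shoulder-like phantom volume and noisy quadric point clouds.

The phantom stands in for a rotator-cuff MRI: a bright spherical shell (the
tendon footprint draped over the humeral head) on a dark background, with a
spherical-cap region of reduced intensity emulating a partial tear.  The cap's
solid angle is known in closed form, so end-to-end texturing runs have an
exact oracle: the fraction of low-intensity points on a uniformly sampled
patch must match the cap's share of the patch area.

Everything here is a pure function of its spec and seed (bit-reproducible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .texturing import VoxelVolume


@dataclass
class PhantomSpec:
    """Parameters of the synthetic shoulder phantom.

    The shell is centered on the head sphere: it occupies radii
    ``head_radius ± shell_thickness/2``, so a patch sampled at the head radius
    reads mid-shell gray values.  The tear is the spherical cap of angular
    radius ``tear_angular_radius`` around the direction given by
    ``tear_center_angles = (azimuth, elevation)`` in radians.  Intensities are
    well separated (defaults 20/200/60, noise sigma 5) so fraction checks need
    no tuned threshold.
    """

    dims: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    head_center: tuple[float, float, float] = (63.5, 63.5, 63.5)
    head_radius: float = 24.0
    shell_thickness: float = 4.0
    shell_intensity: float = 200.0
    background_intensity: float = 20.0
    tear_intensity: float = 60.0
    tear_center_angles: tuple[float, float] = (0.0, math.pi / 2)  # azimuth, elevation
    tear_angular_radius: float = 0.5
    noise_sigma: float = 5.0
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.head_radius > self.shell_thickness > 0:
            raise ValueError("need head_radius > shell_thickness > 0")
        if not 0 < self.tear_angular_radius < math.pi / 2:
            raise ValueError("tear_angular_radius must lie in (0, pi/2)")

    @property
    def tear_direction(self) -> np.ndarray:
        az, el = self.tear_center_angles
        return np.array([math.cos(el) * math.cos(az),
                         math.cos(el) * math.sin(az),
                         math.sin(el)])

    @property
    def cap_solid_angle_fraction(self) -> float:
        """Cap area as a fraction of the full sphere: ``(1 - cos(theta))/2``."""
        return (1.0 - math.cos(self.tear_angular_radius)) / 2.0

    @property
    def cap_hemisphere_fraction(self) -> float:
        """Cap area as a fraction of a hemisphere patch that contains it whole."""
        return 1.0 - math.cos(self.tear_angular_radius)

    def to_config(self) -> str:
        """Flat key-value serialization (matches the patch-spec config dialect)."""
        parts = []
        for name in ("dims", "spacing", "head_center", "tear_center_angles", "origin"):
            vals = getattr(self, name)
            parts.append(f"{name} = " + " ".join(f"{v:.17g}" for v in vals) + "\n")
        for name in ("head_radius", "shell_thickness", "shell_intensity",
                     "background_intensity", "tear_intensity", "tear_angular_radius",
                     "noise_sigma", "seed"):
            parts.append(f"{name} = {getattr(self, name):.17g}\n")
        return "".join(parts)


def synthetic_shoulder_volume(spec: PhantomSpec) -> VoxelVolume:
    """Render the phantom onto a voxel grid.

    Voxel membership is decided at voxel centers, in set-exclusive order:
    background everywhere, shell where the center-distance lies within the
    shell band, tear where additionally the angle to the tear direction is at
    most the tear's angular radius.  Seeded Gaussian noise is added last.
    """
    dims = spec.dims
    spacing = np.asarray(spec.spacing, dtype=float)
    origin = np.asarray(spec.origin, dtype=float)
    center = np.asarray(spec.head_center, dtype=float)
    r_out = spec.head_radius + spec.shell_thickness / 2.0
    lo_corner = origin
    hi_corner = origin + (np.array(dims) - 1) * spacing
    if np.any(center - r_out < lo_corner) or np.any(center + r_out > hi_corner):
        raise ValueError("phantom head+shell does not fit inside the volume")

    ax = [origin[k] + spacing[k] * np.arange(dims[k]) - center[k] for k in range(3)]
    dx = ax[0][:, None, None]
    dy = ax[1][None, :, None]
    dz = ax[2][None, None, :]
    r = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    values = np.full(dims, spec.background_intensity, dtype=float)
    in_shell = (r >= spec.head_radius - spec.shell_thickness / 2.0) & (r <= r_out)
    values[in_shell] = spec.shell_intensity
    d = spec.tear_direction
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_angle = (dx * d[0] + dy * d[1] + dz * d[2]) / np.where(r > 0, r, np.inf)
    in_tear = in_shell & (cos_angle >= math.cos(spec.tear_angular_radius))
    values[in_tear] = spec.tear_intensity
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values += rng.normal(0.0, spec.noise_sigma, size=dims)
    return VoxelVolume(values=values, spacing=spacing, origin=origin)


def noisy_sphere_points(center, radius: float, n: int, sigma: float,
                        seed: int) -> np.ndarray:
    """``n`` points uniform on the sphere (isotropic-Gaussian normalization)
    with radial Gaussian noise of standard deviation ``sigma``."""
    if n < 4:
        raise ValueError("need n >= 4")
    if radius <= 0 or sigma < 0:
        raise ValueError("radius must be positive and sigma nonnegative")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = np.full(n, float(radius))
    if sigma > 0:
        radii += rng.standard_normal(n) * sigma
    return np.asarray(center, dtype=float) + dirs * radii[:, None]


def noisy_spheroid_points(center, a1: float, a2: float, axis, n: int, sigma: float,
                          seed: int) -> np.ndarray:
    """Points on an ellipsoid of revolution (semiaxis ``a1`` along ``axis``,
    ``a2`` transverse) with isotropic Gaussian coordinate noise ``sigma``."""
    if n < 6:
        raise ValueError("need n >= 6")
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    naxis = np.asarray(axis, dtype=float)
    naxis = naxis / np.linalg.norm(naxis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(naxis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(naxis, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(naxis, t1)
    u = dirs @ naxis
    w1 = dirs @ t1
    w2 = dirs @ t2
    pts = (np.asarray(center, dtype=float)
           + np.outer(a1 * u, naxis) + np.outer(a2 * w1, t1) + np.outer(a2 * w2, t2))
    if sigma > 0:
        pts = pts + rng.standard_normal((n, 3)) * sigma
    return pts
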