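"""Quadric fitting to anatomical point clouds and gray-value texturing of surfaces.

The visualization pipeline fits a sphere (or ellipsoid of revolution) to
landmark points on the humerus head, samples the fitted patch, and assigns each
surface point a gray level by trilinear interpolation from a 3-D scalar volume.

Coordinate convention (documented because it is easy to get silently wrong):
voxel indices are 0-based, ``world = origin + index * spacing`` addresses voxel
*centers*, and the interpolable box ends at the outermost voxel centers — no
extrapolation.  Volumes are axis-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with spacing and origin defining a world gray-value field."""

    values: np.ndarray               # (nx, ny, nz) scalar grid
    spacing: np.ndarray              # (3,) voxel size per axis (mm)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # world pos of voxel (0,0,0) center

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive per axis")
        if min(self.values.shape) < 2:
            raise ValueError("each axis needs >= 2 voxels (trilinear needs a cell)")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (voxel-center convention)."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where points lie within the interpolable box (outermost voxel centers)."""
        c = self.world_to_voxel(points)
        hi = np.array(self.dims) - 1
        return np.all((c >= 0) & (c <= hi), axis=1)

    def save(self, path) -> None:
        from . import io as _io
        _io.write_volume(path, self)

    @classmethod
    def load(cls, path) -> "VoxelVolume":
        from . import io as _io
        return _io.read_volume(path)


@dataclass
class TexturedCloud:
    """Surface points with interpolated gray values; ``gray`` is only meaningful
    where ``inside_mask`` is true (out-of-box points are flagged, never dropped)."""

    points: np.ndarray
    gray: np.ndarray
    inside_mask: np.ndarray

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def to_csv(self, path) -> None:
        from . import io as _io
        _io.write_textured_csv(path, self.points, self.gray, self.inside_mask)

    def to_ply(self, path) -> None:
        from . import io as _io
        _io.write_ply_points(path, self.points, gray=self.gray)


@dataclass
class FittedQuadric:
    """Least-squares fit result: center, semiaxes ``(a1, a2, a3)`` and residual."""

    center: np.ndarray
    semiaxes: tuple[float, float, float]
    kind: str                      # "sphere" | "revolution"
    rss: float
    axis: np.ndarray | None = None  # symmetry axis (revolution fits)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if min(self.semiaxes) <= 0:
            raise ValueError("fitted semiaxes must be positive")
        if self.kind == "sphere" and len(set(self.semiaxes)) != 1:
            raise ValueError("a sphere fit must have equal semiaxes")

    @property
    def radius(self) -> float:
        return self.semiaxes[0]


# ---------------------------------------------------------------------------
# trilinear interpolation
# ---------------------------------------------------------------------------

def _interp(volume: VoxelVolume, coords: np.ndarray) -> np.ndarray:
    # order=1 spline interpolation IS the trilinear blend of the 8 cell corners
    return ndimage.map_coordinates(volume.values.astype(float), coords.T,
                                   order=1, mode="nearest")


def trilinear_sample(volume: VoxelVolume, p) -> float:
    """Gray value at one world point by trilinear interpolation.

    The point is converted to continuous voxel coordinates and blended over
    the 8 corners of its enclosing cell.  Points outside the interpolable box
    raise :class:`DomainError`; use :func:`texture_points` for per-point
    flagging in batch mode.
    """
    pa = np.atleast_2d(np.asarray(p, dtype=float))
    if pa.shape != (1, 3):
        raise ValueError("trilinear_sample takes a single 3-D point")
    if not volume.contains(pa)[0]:
        raise DomainError("point outside the volume's interpolable box")
    return float(_interp(volume, volume.world_to_voxel(pa))[0])


def texture_points(volume: VoxelVolume, points) -> TexturedCloud:
    """Trilinear gray values for a batch of world points.

    Out-of-box points are flagged through ``inside_mask`` (gray set to NaN)
    rather than dropped, so ``len(cloud.points) == len(points)`` always.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        return TexturedCloud(points=pts, gray=np.empty(0), inside_mask=np.empty(0, bool))
    inside = volume.contains(pts)
    gray = np.full(pts.shape[0], np.nan)
    if np.any(inside):
        gray[inside] = _interp(volume, volume.world_to_voxel(pts[inside]))
    return TexturedCloud(points=pts, gray=gray, inside_mask=inside)


# ---------------------------------------------------------------------------
# least-squares quadric fitting
# ---------------------------------------------------------------------------

def fit_sphere_lsq(points) -> FittedQuadric:
    """Algebraic least-squares sphere fit.

    Solves the linear system ``x^2+y^2+z^2 = 2 c·p + (r^2 - |c|^2)`` for the
    center and the radius term.  Needs at least four non-coplanar points.
    ``rss`` is the sum of squared radial residuals ``(|p - c| - r)^2``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 4:
        raise ValueError("sphere fitting needs at least 4 points")
    A = np.column_stack([2.0 * pts, np.ones(pts.shape[0])])
    b = np.sum(pts ** 2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise np.linalg.LinAlgError(
            "degenerate (coplanar or coincident) point configuration for a sphere fit")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise np.linalg.LinAlgError("sphere fit collapsed to nonpositive radius")
    r = float(np.sqrt(r2))
    rss = float(np.sum((np.linalg.norm(pts - center, axis=1) - r) ** 2))
    return FittedQuadric(center=center, semiaxes=(r, r, r), kind="sphere", rss=rss)


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("axis must be a nonzero vector")
    n = n / norm
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return n, t1, t2


def fit_ellipsoid_revolution_lsq(points, axis=(0.0, 0.0, 1.0)) -> FittedQuadric:
    """Least-squares ellipsoid of revolution with a *given* symmetry axis.

    In the frame ``(n, t1, t2)`` with ``u = p·n`` and transverse part ``v``,
    the surface is ``(u - cu)^2/a1^2 + |v - cv|^2/a2^2 = 1``.  Multiplying by
    ``a1^2`` gives a model linear in ``(rho, b, c1, c2, d)``:

    ``u^2 + rho*|v|^2 + b*u + c1*(v·t1) + c2*(v·t2) + d = 0``,  ``rho = a1^2/a2^2``,

    solved by ordinary least squares; the center and semiaxes are read back
    from the coefficients.  ``a1`` is the semiaxis along the symmetry axis.
    ``rss`` is the residual sum of squares of this algebraic model.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 6:
        raise ValueError("revolution-ellipsoid fitting needs at least 6 points")
    n, t1, t2 = _orthonormal_basis(np.asarray(axis, dtype=float))
    u = pts @ n
    w1 = pts @ t1
    w2 = pts @ t2
    v2 = w1 ** 2 + w2 ** 2
    A = np.column_stack([v2, u, w1, w2, np.ones_like(u)])
    rhs = -u ** 2
    sol, res, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 5:
        raise np.linalg.LinAlgError("degenerate point configuration for a revolution fit")
    rho, b, c1, c2, d = sol
    if rho <= 0:
        raise np.linalg.LinAlgError("fit is not an ellipsoid (nonpositive axis ratio)")
    cu = -b / 2.0
    cv1 = -c1 / (2.0 * rho)
    cv2 = -c2 / (2.0 * rho)
    K = cu ** 2 + rho * (cv1 ** 2 + cv2 ** 2) - d
    if K <= 0:
        raise np.linalg.LinAlgError("fit is not an ellipsoid (nonpositive size term)")
    a1 = float(np.sqrt(K))
    a2 = float(np.sqrt(K / rho))
    center = cu * n + cv1 * t1 + cv2 * t2
    resid = A @ sol - rhs
    return FittedQuadric(center=center, semiaxes=(a1, a2, a2), kind="revolution",
                         rss=float(resid @ resid), axis=n)
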