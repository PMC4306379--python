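"""Ellipsoidal surface patches: domain, graph, surface-uniform density, change of variables.

A patch is the graph of ``x3 = a3*sqrt(1 - (x1/a1)^2 - (x2/a2)^2)`` on the planar
domain ``D`` cut out of the upper half-ellipsoid with semiaxes ``a1 >= a2 >= a3 > 0``
by lateral bounds ``alpha2 < x2/(a2*sqrt(1-(x1/a1)^2)) < alpha1`` and longitudinal
bounds ``beta2 < x1 < beta1``.

A random point on the surface is *surface-uniform* when the probability of any
region is proportional to its surface area.  The planar density that realizes this
is ``f`` (:func:`density_f`), and the change of variables ``g`` maps ``D`` onto the
rectangle ``D_g = (beta2/a1, beta1/a1) x (alpha2, alpha1)`` where the transformed
density ``f_g`` (:func:`density_fg`) factorizes for spheres and ellipsoids of
revolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import integrate

from .errors import DomainError, QuadratureError, SpecError

#: relative tolerance used to classify sphere / ellipsoid-of-revolution shapes
SHAPE_TOL = 1e-12

#: points within this distance of the domain boundary are clamped onto it
BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class EllipsoidPatchSpec:
    """Semiaxes and domain bounds defining a patch on the upper half-ellipsoid.

    Parameters
    ----------
    a1, a2, a3:
        Semiaxis lengths, ``a1 >= a2 >= a3 > 0`` (length units, e.g. mm).
    alpha1, alpha2:
        Dimensionless lateral bounds, ``|alpha_i| <= 1``, ``alpha2 < alpha1``.
    beta1, beta2:
        Longitudinal bounds along the first axis, ``|beta_i| <= a1``,
        ``beta2 < beta1`` (same units as the semiaxes).
    """

    a1: float
    a2: float
    a3: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        a1, a2, a3 = self.a1, self.a2, self.a3
        if not (a1 > 0 and a2 > 0 and a3 > 0):
            raise SpecError("semiaxes must be strictly positive")
        if not (a1 >= a2 >= a3):
            raise SpecError(f"semiaxes must satisfy a1 >= a2 >= a3, got {a1}, {a2}, {a3}")
        for name in ("alpha1", "alpha2"):
            if abs(getattr(self, name)) > 1:
                raise SpecError(f"|{name}| must be <= 1")
        for name in ("beta1", "beta2"):
            if abs(getattr(self, name)) > a1:
                raise SpecError(f"|{name}| must be <= a1")
        if not self.alpha2 < self.alpha1:
            raise SpecError("alpha2 < alpha1 required for a nondegenerate domain")
        if not self.beta2 < self.beta1:
            raise SpecError("beta2 < beta1 required for a nondegenerate domain")

    # -- derived shape flags -------------------------------------------------

    @property
    def is_sphere(self) -> bool:
        """True when ``a1 = a2 = a3`` within :data:`SHAPE_TOL` (relative)."""
        return (self.a1 - self.a3) <= SHAPE_TOL * self.a1

    @property
    def is_revolution(self) -> bool:
        """True when ``a2 = a3`` within :data:`SHAPE_TOL` (ellipsoid of revolution)."""
        return (self.a2 - self.a3) <= SHAPE_TOL * self.a2

    @property
    def delta1(self) -> float:
        return 1.0 - (self.a3 / self.a1) ** 2

    @property
    def delta2(self) -> float:
        return 1.0 - (self.a3 / self.a2) ** 2

    @property
    def y1_bounds(self) -> tuple[float, float]:
        """The ``y1`` interval of the rectangle ``D_g``."""
        return (self.beta2 / self.a1, self.beta1 / self.a1)

    @property
    def y2_bounds(self) -> tuple[float, float]:
        """The ``y2`` interval of the rectangle ``D_g``."""
        return (self.alpha2, self.alpha1)

    # -- serialization -------------------------------------------------------

    _FIELDS = ("a1", "a2", "a3", "alpha1", "alpha2", "beta1", "beta2")

    def to_config(self) -> str:
        """Serialize to a flat ``key = value`` text block (17 significant digits)."""
        return "".join(f"{k} = {getattr(self, k):.17g}\n" for k in self._FIELDS)

    @classmethod
    def from_config(cls, text: str | Iterable[str]) -> "EllipsoidPatchSpec":
        """Parse the flat key-value block written by :meth:`to_config`."""
        lines = text.splitlines() if isinstance(text, str) else list(text)
        values: dict[str, float] = {}
        for line in lines:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key in cls._FIELDS:
                values[key] = float(val)
        missing = set(cls._FIELDS) - set(values)
        if missing:
            raise SpecError(f"patch config missing keys: {sorted(missing)}")
        return cls(**values)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "EllipsoidPatchSpec":
        return cls(**{k: float(mapping[k]) for k in cls._FIELDS})


def sphere_patch(radius: float = 1.0, *, alpha1: float = 1.0, alpha2: float = -1.0,
                 beta1: float | None = None, beta2: float | None = None) -> EllipsoidPatchSpec:
    """Convenience constructor for a spherical patch (defaults: full upper hemisphere)."""
    b1 = radius if beta1 is None else beta1
    b2 = -radius if beta2 is None else beta2
    return EllipsoidPatchSpec(radius, radius, radius, alpha1, alpha2, b1, b2)


@dataclass
class ShapeParams:
    """Dimensionless shape parameters of a patch.

    ``delta1 = 1 - (a3/a1)^2`` and ``delta2 = 1 - (a3/a2)^2`` satisfy
    ``1 > delta1 >= delta2 >= 0``; ``kappa = 1/area(s(D))`` normalizes the
    surface-uniform density and is computed lazily (``None`` until requested).
    """

    delta1: float
    delta2: float
    kappa: float | None = field(default=None)


def shape_deltas(spec: EllipsoidPatchSpec, *, with_kappa: bool = False) -> ShapeParams:
    """Shape parameters ``(delta1, delta2)`` and, optionally, the normalization ``kappa``.

    With ``with_kappa=True`` the patch area is computed by quadrature and
    ``kappa = 1/area``; otherwise ``kappa`` is left unset, which is all the
    samplers need (they work with density ratios only).
    """
    kappa = 1.0 / patch_area(spec) if with_kappa else None
    return ShapeParams(delta1=spec.delta1, delta2=spec.delta2, kappa=kappa)


# ---------------------------------------------------------------------------
# surface graph and change of variables
# ---------------------------------------------------------------------------

def _in_domain_xy(spec: EllipsoidPatchSpec, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Elementwise membership of (x1, x2) in the closure of D (with clamping slack)."""
    t = (x1 / spec.a1) ** 2 + (x2 / spec.a2) ** 2
    w = np.sqrt(np.clip(1.0 - (x1 / spec.a1) ** 2, 0.0, None))
    lat = x2 / np.where(spec.a2 * w > 0, spec.a2 * w, np.inf)
    ok = (t <= 1.0 + BOUNDARY_TOL)
    ok &= (x1 >= spec.beta2 - BOUNDARY_TOL * spec.a1) & (x1 <= spec.beta1 + BOUNDARY_TOL * spec.a1)
    ok &= (lat >= spec.alpha2 - BOUNDARY_TOL) & (lat <= spec.alpha1 + BOUNDARY_TOL)
    return ok


def surface_point(spec: EllipsoidPatchSpec, x1, x2):
    """Lift planar coordinates to the surface: ``(x1, x2, x3(x1, x2))``.

    Accepts scalars or arrays; the third coordinate is
    ``a3*sqrt(1 - (x1/a1)^2 - (x2/a2)^2) >= 0``.

    Raises
    ------
    DomainError
        If any point lies outside the closure of ``D`` beyond the clamping
        tolerance.
    """
    x1a = np.asarray(x1, dtype=float)
    x2a = np.asarray(x2, dtype=float)
    if not np.all(_in_domain_xy(spec, x1a, x2a)):
        raise DomainError("point outside the patch domain D")
    radicand = 1.0 - (x1a / spec.a1) ** 2 - (x2a / spec.a2) ** 2
    if np.any(radicand < -BOUNDARY_TOL):
        raise DomainError("radicand negative beyond tolerance: point off the ellipse")
    x3 = spec.a3 * np.sqrt(np.clip(radicand, 0.0, None))
    out = np.stack([x1a, x2a, x3], axis=-1)
    return out if out.ndim > 1 else tuple(out)


def map_g(spec: EllipsoidPatchSpec, x1, x2):
    """Forward change of variables ``g: D -> D_g``, ``y1 = x1/a1``, ``y2 = x2/(a2*sqrt(1-y1^2))``."""
    x1a = np.asarray(x1, dtype=float)
    x2a = np.asarray(x2, dtype=float)
    if not np.all(_in_domain_xy(spec, x1a, x2a)):
        raise DomainError("point outside the patch domain D")
    y1 = x1a / spec.a1
    w = np.sqrt(np.clip(1.0 - y1 ** 2, 0.0, None))
    if np.any(w == 0.0):
        raise DomainError("g is singular at |x1| = a1")
    y2 = x2a / (spec.a2 * w)
    return y1, np.clip(y2, -1.0, 1.0)


def _in_domain_y(spec: EllipsoidPatchSpec, y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    lo1, hi1 = spec.y1_bounds
    lo2, hi2 = spec.y2_bounds
    ok = (y1 >= lo1 - BOUNDARY_TOL) & (y1 <= hi1 + BOUNDARY_TOL)
    ok &= (y2 >= lo2 - BOUNDARY_TOL) & (y2 <= hi2 + BOUNDARY_TOL)
    return ok


def map_g_inverse(spec: EllipsoidPatchSpec, y1, y2):
    """Inverse change of variables ``g^{-1}: D_g -> D``.

    ``x1 = a1*y1`` and ``x2 = a2*y2*sqrt(1 - y1^2)``.
    """
    y1a = np.asarray(y1, dtype=float)
    y2a = np.asarray(y2, dtype=float)
    if not np.all(_in_domain_y(spec, y1a, y2a)):
        raise DomainError("point outside the rectangle D_g")
    x1 = spec.a1 * y1a
    x2 = spec.a2 * y2a * np.sqrt(np.clip(1.0 - y1a ** 2, 0.0, None))
    return x1, x2


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def density_f(spec: EllipsoidPatchSpec, x1, x2, *, normalized: bool = False,
              kappa: float | None = None):
    """Surface-uniform planar density ``f`` on ``D``.

    ``f(x) = kappa * sqrt((1 - d1*(x1/a1)^2 - d2*(x2/a2)^2) / (1 - (x1/a1)^2 - (x2/a2)^2))``

    with ``kappa = 1/area`` when ``normalized`` (computed by quadrature unless
    supplied), else ``kappa = 1``.  The density has an integrable singularity on
    the equator ellipse; evaluating there raises :class:`DomainError`.
    """
    x1a = np.asarray(x1, dtype=float)
    x2a = np.asarray(x2, dtype=float)
    if not np.all(_in_domain_xy(spec, x1a, x2a)):
        raise DomainError("point outside the patch domain D")
    u = (x1a / spec.a1) ** 2
    v = (x2a / spec.a2) ** 2
    denom = 1.0 - u - v
    if np.any(denom <= 0.0):
        raise DomainError(
            "density_f is singular on the equator ellipse (1 - (x1/a1)^2 - (x2/a2)^2 <= 0)")
    num = 1.0 - spec.delta1 * u - spec.delta2 * v
    k = 1.0
    if normalized:
        k = kappa if kappa is not None else 1.0 / patch_area(spec)
    out = k * np.sqrt(num / denom)
    return float(out) if out.ndim == 0 else out


def density_fg(spec: EllipsoidPatchSpec, y1, y2, *, normalized: bool = False,
               kappa: float | None = None):
    """Density of ``Y = g(X)`` on the rectangle ``D_g``.

    ``f_g(y) = kappa * a1 * a2 * sqrt((1 - d1*y1^2) * (1 - m(y1)*y2^2) / (1 - y2^2))``
    with ``m(y1) = d2*(1 - y1^2)/(1 - d1*y1^2)``.
    """
    y1a = np.asarray(y1, dtype=float)
    y2a = np.asarray(y2, dtype=float)
    if not np.all(_in_domain_y(spec, y1a, y2a)):
        raise DomainError("point outside the rectangle D_g")
    if np.any(np.abs(y2a) >= 1.0):
        raise DomainError("f_g is singular at |y2| = 1")
    d1, d2 = spec.delta1, spec.delta2
    one_m_d1y1 = 1.0 - d1 * y1a ** 2
    m = d2 * (1.0 - y1a ** 2) / one_m_d1y1
    k = 1.0
    if normalized:
        k = kappa if kappa is not None else 1.0 / patch_area(spec)
    out = k * spec.a1 * spec.a2 * np.sqrt(one_m_d1y1 * (1.0 - m * y2a ** 2) / (1.0 - y2a ** 2))
    return float(out) if out.ndim == 0 else out


def log_density_fg(spec: EllipsoidPatchSpec, y1: float, y2: float) -> float:
    """Unnormalized log of :func:`density_fg`; ``-inf`` outside ``D_g``.

    This is the Metropolis–Hastings target: no domain exception, no
    normalization, cheap scalar evaluation.
    """
    lo1, hi1 = spec.y1_bounds
    lo2, hi2 = spec.y2_bounds
    if not (lo1 < y1 < hi1 and lo2 < y2 < hi2) or abs(y2) >= 1.0:
        return -np.inf
    d1, d2 = spec.delta1, spec.delta2
    one_m_d1y1 = 1.0 - d1 * y1 * y1
    m = d2 * (1.0 - y1 * y1) / one_m_d1y1
    return 0.5 * (np.log(one_m_d1y1) + np.log(1.0 - m * y2 * y2) - np.log(1.0 - y2 * y2))


# ---------------------------------------------------------------------------
# patch area
# ---------------------------------------------------------------------------

def patch_area(spec: EllipsoidPatchSpec, *, epsrel: float = 1e-10,
               y1_bounds: tuple[float, float] | None = None,
               y2_bounds: tuple[float, float] | None = None) -> float:
    """Surface area of the patch ``s(D)`` (or a sub-rectangle of ``D_g``) by quadrature.

    The area is the integral of the unnormalized ``f_g`` over ``D_g``.  The
    integrable ``1/sqrt(1 - y2^2)`` endpoint singularity is removed exactly by
    the substitution ``y2 = sin(theta)``, leaving the smooth integrand

    ``a1 * a2 * sqrt((1 - d1*y1^2) * (1 - m(y1)*sin(theta)^2))``

    over ``(theta, y1)`` in ``(arcsin(alpha2), arcsin(alpha1)) x (beta2/a1, beta1/a1)``.
    """
    d1, d2 = spec.delta1, spec.delta2
    lo1, hi1 = y1_bounds if y1_bounds is not None else spec.y1_bounds
    lo2, hi2 = y2_bounds if y2_bounds is not None else spec.y2_bounds
    th_lo, th_hi = np.arcsin(lo2), np.arcsin(hi2)

    def integrand(theta: float, y1: float) -> float:
        one_m_d1y1 = 1.0 - d1 * y1 * y1
        m = d2 * (1.0 - y1 * y1) / one_m_d1y1
        return np.sqrt(one_m_d1y1 * (1.0 - m * np.sin(theta) ** 2))

    val, err = integrate.dblquad(integrand, lo1, hi1, th_lo, th_hi,
                                 epsabs=0.0, epsrel=epsrel)
    area = spec.a1 * spec.a2 * val
    if not np.isfinite(area) or (area > 0 and err / val > 1e-6):
        raise QuadratureError(
            f"patch area quadrature did not converge: value={area!r}, abserr={err!r}")
    return area
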