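"""Surface-uniform random point generation on ellipsoidal patches.

Four generators are provided, all working in the rectangle ``D_g`` and pulled
back to the surface through ``g^{-1}`` and the graph map:

``sample_sphere_inverse``
    Exact inverse-transform sampling for spherical patches: ``y1`` uniform,
    ``y2 = sin`` of a uniform angle.
``sample_revolution_inverse``
    Inverse transform for ellipsoids of revolution; the ``y1`` marginal has
    density proportional to ``sqrt(1 - delta1*y1^2)`` (a scaled semicircular
    law) and is inverted through a monotone-cubic approximation of the
    antiderivative's inverse ``phi^{-1}``.
``sample_ar_y1``
    Acceptance-rejection for the same ``y1`` marginal under a uniform
    envelope; efficiency exactly ``1/c``.
``sample_general_ellipsoid``
    Metropolis–Hastings random walk on the 2-D density ``f_g`` — the only
    route for triaxial ellipsoids, where inverse transforms would require
    elliptic integrals.

Randomness: each batch owns one ``numpy.random.default_rng(seed)`` stream.
Inverse-transform batches draw all ``U1`` variates first, then all ``U2``
(one vectorized call each), so fixed seeds give bit-identical batches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from . import io as _io
from .errors import DomainError, ShapeBranchError
from .patch_geometry import (
    BOUNDARY_TOL,
    EllipsoidPatchSpec,
    map_g_inverse,
    patch_area,
    surface_point,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SampleBatch", "SemicircularTransform", "ARStats", "HastingsConfig",
    "phi", "build_phi_inverse", "sample_sphere_inverse",
    "sample_revolution_inverse", "sample_ar_y1", "sample_revolution_ar", "ar_envelope",
    "hastings_chain", "sample_general_ellipsoid",
    "marginal_cdf_y1", "marginal_cdf_y2",
    "UniformityGrid", "make_uniformity_grid", "uniformity_chi_square",
]


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

@dataclass
class SampleBatch:
    """A seeded batch of surface points carried in y, x and 3-D coordinates."""

    method: str
    seed: int
    y: np.ndarray        # (n, 2) points in D_g
    x: np.ndarray        # (n, 2) points in D
    points: np.ndarray   # (n, 3) points on the ellipsoid surface

    @property
    def n(self) -> int:
        return self.y.shape[0]

    # spec-facing aliases
    @property
    def y_points(self) -> np.ndarray:
        return self.y

    @property
    def x_points(self) -> np.ndarray:
        return self.x

    @property
    def surface_points(self) -> np.ndarray:
        return self.points

    def quadric_residual(self, spec: EllipsoidPatchSpec) -> float:
        """Max of ``|(px/a1)^2 + (py/a2)^2 + (pz/a3)^2 - 1|`` over the batch."""
        p = self.points
        q = (p[:, 0] / spec.a1) ** 2 + (p[:, 1] / spec.a2) ** 2 + (p[:, 2] / spec.a3) ** 2
        return float(np.max(np.abs(q - 1.0))) if self.n else 0.0

    def to_csv(self, path) -> None:
        _io.write_batch_csv(path, self.method, self.seed, self.y, self.x, self.points)

    def to_ply(self, path) -> None:
        _io.write_ply_points(path, self.points)


def _batch_from_y(spec: EllipsoidPatchSpec, method: str, seed: int,
                  y1: np.ndarray, y2: np.ndarray) -> SampleBatch:
    lo1, hi1 = spec.y1_bounds
    lo2, hi2 = spec.y2_bounds
    y1 = np.clip(y1, lo1, hi1)
    y2 = np.clip(y2, lo2, hi2)
    x1, x2 = map_g_inverse(spec, y1, y2)
    pts = surface_point(spec, x1, x2)
    return SampleBatch(method=method, seed=seed,
                       y=np.column_stack([y1, y2]),
                       x=np.column_stack([x1, x2]),
                       points=np.asarray(pts))


# ---------------------------------------------------------------------------
# the antiderivative phi and its tabulated inverse
# ---------------------------------------------------------------------------

def phi(t, delta1: float):
    """Antiderivative of ``sqrt(1 - delta1*t^2)`` with ``phi(0; delta1) = 0``.

    ``phi(t; d) = (sqrt(d)*t*sqrt(1 - d*t^2) + arcsin(sqrt(d)*t)) / (2*sqrt(d))``.

    Strictly increasing on ``|t| <= 1/sqrt(delta1)``; drives the
    inverse-transform sampler for ellipsoids of revolution.
    """
    if not 0.0 < delta1 <= 1.0:
        if delta1 == 0.0:
            raise ShapeBranchError(
                "phi degenerates to the identity at delta1=0; use the sphere branch")
        raise DomainError(f"delta1 must lie in (0, 1], got {delta1}")
    ta = np.asarray(t, dtype=float)
    rd = math.sqrt(delta1)
    s = rd * ta
    if np.any(np.abs(s) > 1.0 + 1e-12):
        raise DomainError("|t|*sqrt(delta1) must be <= 1")
    s = np.clip(s, -1.0, 1.0)
    out = (s * np.sqrt(1.0 - s * s) + np.arcsin(s)) / (2.0 * rd)
    return float(out) if out.ndim == 0 else out


@dataclass
class SemicircularTransform:
    """Tabulated inverse ``phi^{-1}(.; 1)`` of the semicircular-law antiderivative.

    ``knots`` are strictly increasing abscissae ``phi(s_k; 1)`` covering
    ``[-pi/4, pi/4]``; ``values`` the matching ``s_k`` in ``[-1, 1]``.  The
    monotone piecewise-cubic Hermite interpolant maps
    ``u -> phi^{-1}(u; 1)`` without overshoot.  ``r1``/``r2`` record, when the
    transform is attached to a patch, the endpoints ``r_i = sqrt(delta1)*beta_i/a1``
    of the scaled variable ``Z = sqrt(delta1)*Y1``.
    """

    knots: np.ndarray
    values: np.ndarray
    n_knots: int
    interp: PchipInterpolator = field(repr=False)
    r1: float | None = None
    r2: float | None = None

    def __call__(self, u):
        u = np.clip(u, self.knots[0], self.knots[-1])
        out = np.clip(self.interp(u), -1.0, 1.0)
        return float(out) if np.ndim(out) == 0 else out

    def max_residual(self, n_probes: int = 100_000) -> float:
        """``max_u |phi(interp(u); 1) - u|`` over a dense uniform probe grid."""
        u = np.linspace(self.knots[0], self.knots[-1], n_probes)
        return float(np.max(np.abs(phi(self(u), 1.0) - u)))


@lru_cache(maxsize=8)
def build_phi_inverse(n_knots: int = 200) -> SemicircularTransform:
    """Tabulate ``phi(.; 1)`` at Chebyshev–Lobatto abscissae and invert monotonically.

    The knots ``s_k = -cos(pi*k/(n-1))`` cluster near ``s = ±1`` where
    ``phi'`` vanishes and the inverse steepens, which is where interpolation
    accuracy is hardest to hold.  The swapped data ``(phi(s_k;1), s_k)`` is
    monotone, so the shape-preserving cubic Hermite scheme (PCHIP) yields a
    monotone interpolant with no overshoot.
    """
    if n_knots < 4:
        raise ValueError("n_knots must be >= 4")
    k = np.arange(n_knots)
    s = -np.cos(np.pi * k / (n_knots - 1))
    u = phi(s, 1.0)
    interp = PchipInterpolator(u, s, extrapolate=False)
    return SemicircularTransform(knots=u, values=s, n_knots=n_knots, interp=interp)


# ---------------------------------------------------------------------------
# inverse-transform samplers
# ---------------------------------------------------------------------------

def _draw_y2(spec: EllipsoidPatchSpec, u2: np.ndarray) -> np.ndarray:
    # y2 = sin(U*arcsin(a1) + (1-U)*arcsin(a2)): shared by every shape branch
    t1, t2 = math.asin(spec.alpha1), math.asin(spec.alpha2)
    return np.sin(u2 * t1 + (1.0 - u2) * t2)


def sample_sphere_inverse(spec: EllipsoidPatchSpec, n: int, seed: int) -> SampleBatch:
    """Exact inverse-transform sampling on a spherical patch.

    ``y1 = (beta1*U1 + beta2*(1-U1))/a1`` (uniform on its interval) and
    ``y2 = sin(U2*arcsin(alpha1) + (1-U2)*arcsin(alpha2))``, with independent
    uniform variates ``U1, U2``.
    """
    if not spec.is_sphere:
        raise ShapeBranchError(
            "sample_sphere_inverse requires a1=a2=a3; use sample_revolution_inverse "
            "or sample_general_ellipsoid for this patch")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u1 = rng.random(n)
    u2 = rng.random(n)
    y1 = (spec.beta1 * u1 + spec.beta2 * (1.0 - u1)) / spec.a1
    y2 = _draw_y2(spec, u2)
    return _batch_from_y(spec, "sphere_inverse", seed, y1, y2)


def semicircular_endpoints(spec: EllipsoidPatchSpec) -> tuple[float, float]:
    """Endpoints ``(r1, r2)`` of ``Z = sqrt(delta1)*Y1``: ``r_i = sqrt(delta1)*beta_i/a1``."""
    rd = math.sqrt(spec.delta1)
    return rd * spec.beta1 / spec.a1, rd * spec.beta2 / spec.a1


def sample_revolution_inverse(spec: EllipsoidPatchSpec, n: int, seed: int,
                              transform: SemicircularTransform | None = None) -> SampleBatch:
    """Inverse-transform sampling on an ellipsoid-of-revolution patch.

    ``y2`` is drawn exactly as in the sphere case.  For ``y1``, the scaled
    variable ``Z = sqrt(delta1)*Y1`` follows the semicircular law restricted to
    ``(r2, r1)``; it is drawn as ``Z = phi^{-1}(U*phi(r1;1) + (1-U)*phi(r2;1); 1)``
    through the tabulated monotone inverse, then ``y1 = Z/sqrt(delta1)``.
    """
    if spec.is_sphere:
        raise ShapeBranchError("patch is a sphere; use sample_sphere_inverse")
    if not spec.is_revolution:
        raise ShapeBranchError(
            "sample_revolution_inverse requires a2=a3; use sample_general_ellipsoid")
    if n < 1:
        raise ValueError("n must be >= 1")
    tr = transform if transform is not None else build_phi_inverse()
    r1, r2 = semicircular_endpoints(spec)
    p1, p2 = phi(r1, 1.0), phi(r2, 1.0)
    rng = np.random.default_rng(seed)
    u1 = rng.random(n)
    u2 = rng.random(n)
    z = tr(u1 * p1 + (1.0 - u1) * p2)
    y1 = z / math.sqrt(spec.delta1)
    y2 = _draw_y2(spec, u2)
    return _batch_from_y(spec, "revolution_inverse", seed, y1, y2)


# ---------------------------------------------------------------------------
# marginal CDFs (oracles for the inverse samplers, targets for KS tests)
# ---------------------------------------------------------------------------

def marginal_cdf_y1(spec: EllipsoidPatchSpec, y):
    """Analytic CDF of the ``y1`` marginal of ``f_g`` on ``(beta2/a1, beta1/a1)``.

    Uniform for spheres; otherwise ``(phi(y;d1) - phi(lo;d1)) / (phi(hi;d1) - phi(lo;d1))``.
    """
    lo, hi = spec.y1_bounds
    ya = np.clip(np.asarray(y, dtype=float), lo, hi)
    if spec.is_sphere:
        out = (ya - lo) / (hi - lo)
    else:
        d1 = spec.delta1
        plo, phi_hi = phi(lo, d1), phi(hi, d1)
        out = (phi(ya, d1) - plo) / (phi_hi - plo)
    return float(out) if np.ndim(out) == 0 else out


def marginal_cdf_y2(spec: EllipsoidPatchSpec, y):
    """Analytic CDF of the ``y2`` marginal: ``(arcsin y - arcsin alpha2)/(arcsin alpha1 - arcsin alpha2)``."""
    lo, hi = spec.y2_bounds
    ya = np.clip(np.asarray(y, dtype=float), lo, hi)
    t1, t2 = math.asin(hi), math.asin(lo)
    out = (np.arcsin(ya) - t2) / (t1 - t2)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# acceptance-rejection for the y1 marginal (ellipsoid of revolution)
# ---------------------------------------------------------------------------

@dataclass
class ARStats:
    """Envelope constant and proposal bookkeeping of an acceptance-rejection run.

    The method's efficiency — the probability of accepting a proposal — is
    exactly ``1/c``.
    """

    c: float
    f_star: float
    n_proposed: int
    n_accepted: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else float("nan")


def ar_envelope(spec: EllipsoidPatchSpec) -> tuple[float, float, float]:
    """Envelope constant for uniform-proposal acceptance-rejection on the ``y1`` marginal.

    Returns ``(c, f_star, y_star)`` where ``f_star`` is the maximum of the
    normalized marginal density ``f_{g,1}(y) = sqrt(1 - delta1*y^2) / dphi``
    (``dphi`` the normalizing integral via :func:`phi`), attained at
    ``y_star = 0`` when ``0`` lies in the interval and at the endpoint of
    larger density otherwise, and ``c = (beta1 - beta2)/a1 * f_star``.
    """
    if spec.is_sphere:
        raise ShapeBranchError(
            "the y1 marginal of a sphere is uniform: acceptance-rejection is "
            "unnecessary (c=1, efficiency 1); use sample_sphere_inverse")
    lo, hi = spec.y1_bounds
    d1 = spec.delta1
    dphi = phi(hi, d1) - phi(lo, d1)
    if lo < 0.0 < hi:
        y_star = 0.0
    else:
        y_star = lo if math.sqrt(1 - d1 * lo * lo) >= math.sqrt(1 - d1 * hi * hi) else hi
    f_star = math.sqrt(1.0 - d1 * y_star * y_star) / dphi
    c = (hi - lo) * f_star
    return c, f_star, y_star


def sample_ar_y1(spec: EllipsoidPatchSpec, n: int, seed: int) -> tuple[np.ndarray, ARStats]:
    """Draw the ``y1`` marginal by acceptance-rejection under a uniform envelope.

    Proposes ``Y`` uniform on ``(beta2/a1, beta1/a1)`` and accepts with
    probability ``sqrt(1 - delta1*Y^2)/sqrt(1 - delta1*y_star^2)``; loops until
    exactly ``n`` are accepted.  Per chunk, all proposals are drawn before all
    acceptance variates.  Returns the samples and :class:`ARStats` (the
    proposal count covers proposals up to and including the n-th acceptance).
    """
    if spec.is_sphere:
        raise ShapeBranchError(
            "the y1 marginal of a sphere is uniform; acceptance-rejection is unnecessary")
    if n < 1:
        raise ValueError("n must be >= 1")
    c, f_star, y_star = ar_envelope(spec)
    lo, hi = spec.y1_bounds
    d1 = spec.delta1
    peak = math.sqrt(1.0 - d1 * y_star * y_star)
    rng = np.random.default_rng(seed)
    out: list[np.ndarray] = []
    n_kept = 0
    n_proposed = 0
    while n_kept < n:
        chunk = max(1024, int(1.2 * c * (n - n_kept)))
        y = lo + (hi - lo) * rng.random(chunk)
        u = rng.random(chunk)
        acc = u <= np.sqrt(1.0 - d1 * y * y) / peak
        kept = y[acc]
        if n_kept + kept.size >= n:
            need = n - n_kept
            # proposals consumed up to and including the need-th acceptance
            idx = np.flatnonzero(acc)[need - 1]
            n_proposed += int(idx) + 1
            out.append(kept[:need])
            n_kept = n
        else:
            n_proposed += chunk
            out.append(kept)
            n_kept += kept.size
    samples = np.concatenate(out)
    return samples, ARStats(c=c, f_star=f_star, n_proposed=n_proposed, n_accepted=n)


def sample_revolution_ar(spec: EllipsoidPatchSpec, n: int, seed: int
                         ) -> tuple[SampleBatch, ARStats]:
    """Full surface batch on an ellipsoid of revolution with ``y1`` drawn by
    acceptance-rejection and ``y2`` by the exact inverse transform.

    The two marginals are independent, so combining the AR-drawn ``y1`` with
    inverse-transform ``y2`` (drawn from a fresh substream after the AR loop)
    gives the same joint law as :func:`sample_revolution_inverse`.
    """
    y1, ar_stats = sample_ar_y1(spec, n, seed)
    rng = np.random.default_rng((seed, 1))
    y2 = _draw_y2(spec, rng.random(n))
    batch = _batch_from_y(spec, "acceptance_rejection", seed, y1, y2)
    return batch, ar_stats


# ---------------------------------------------------------------------------
# Metropolis–Hastings
# ---------------------------------------------------------------------------

@dataclass
class HastingsConfig:
    """Tuning of the Metropolis–Hastings chain on ``D_g``.

    ``proposal_step`` scales the symmetric Gaussian random walk per dimension
    (absolute units in ``y``-space).  ``proposal="independent"`` switches the
    instrumental density to uniform-on-``D_g`` independence proposals (the
    acceptance ratio then still reduces to the density ratio).  Proposals
    landing outside ``D_g`` have zero target density and are rejected.
    """

    proposal_step: tuple[float, float]
    burn_in: int = 2000
    thin: int = 1
    x0: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    proposal: str = "rw_gauss"
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.proposal not in ("rw_gauss", "independent"):
            raise ValueError(f"unknown proposal kind {self.proposal!r}")
        if self.proposal == "independent" and self.bounds is None:
            raise ValueError("independence proposals need explicit bounds")


def default_hastings_config(spec: EllipsoidPatchSpec, seed: int = 0,
                            **overrides) -> HastingsConfig:
    """Random-walk defaults for a patch: step 0.25x the domain widths, start at center."""
    lo1, hi1 = spec.y1_bounds
    lo2, hi2 = spec.y2_bounds
    cfg = dict(
        proposal_step=(0.25 * (hi1 - lo1), 0.25 * (hi2 - lo2)),
        burn_in=2000,
        thin=1,
        x0=(0.5 * (lo1 + hi1), 0.5 * (lo2 + hi2)),
        seed=seed,
        bounds=((lo1, hi1), (lo2, hi2)),
    )
    cfg.update(overrides)
    return HastingsConfig(**cfg)


def hastings_chain(log_target, config: HastingsConfig, n: int) -> tuple[np.ndarray, float]:
    """Run a Metropolis–Hastings chain and return post-burn-in, thinned samples.

    ``log_target(y1, y2)`` must return the unnormalized log target density
    (``-inf`` outside its support).  The acceptance probability is
    ``rho = min(1, pi(x')*q(x|x') / (pi(x)*q(x'|x)))``; both supported proposal
    kinds are symmetric in the relevant sense, so ``rho`` reduces to the
    target-density ratio.  Returns ``(samples, acceptance_rate)`` with
    ``samples`` of shape ``(n, 2)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x1, x2 = float(config.x0[0]), float(config.x0[1])
    lp = log_target(x1, x2)
    if not np.isfinite(lp):
        raise ValueError("log_target is not finite at the initial point x0")
    total = config.burn_in + n * config.thin
    rng = np.random.default_rng(config.seed)
    log_u = np.log(rng.random(total))
    if config.proposal == "rw_gauss":
        s1, s2 = config.proposal_step
        steps = rng.standard_normal((total, 2))
        steps[:, 0] *= s1
        steps[:, 1] *= s2
        prop1 = None
    else:  # independence proposals, uniform on the given bounds
        (lo1, hi1), (lo2, hi2) = config.bounds
        u = rng.random((total, 2))
        prop1 = np.empty((total, 2))
        prop1[:, 0] = lo1 + (hi1 - lo1) * u[:, 0]
        prop1[:, 1] = lo2 + (hi2 - lo2) * u[:, 1]
        steps = None
    out = np.empty((n, 2))
    n_accept = 0
    k = 0
    burn_in, thin = config.burn_in, config.thin
    for t in range(total):
        if steps is not None:
            c1 = x1 + steps[t, 0]
            c2 = x2 + steps[t, 1]
        else:
            c1 = prop1[t, 0]
            c2 = prop1[t, 1]
        lp_new = log_target(c1, c2)
        if lp_new - lp >= log_u[t]:
            x1, x2, lp = c1, c2, lp_new
            n_accept += 1
        if t >= burn_in and (t - burn_in) % thin == 0:
            out[k, 0] = x1
            out[k, 1] = x2
            k += 1
    rate = n_accept / total
    if not 0.01 < rate < 0.99:
        logger.warning("Hastings acceptance rate %.3f outside (0.01, 0.99); "
                       "consider retuning proposal_step", rate)
    return out, rate


def _fast_log_fg(spec: EllipsoidPatchSpec):
    """Scalar unnormalized log f_g closure using math.* (hot path of the chain)."""
    lo1, hi1 = spec.y1_bounds
    lo2, hi2 = spec.y2_bounds
    d1, d2 = spec.delta1, spec.delta2
    neg_inf = float("-inf")
    log, sqrt = math.log, math.sqrt

    def log_target(y1: float, y2: float) -> float:
        if not (lo1 < y1 < hi1 and lo2 < y2 < hi2) or abs(y2) >= 1.0:
            return neg_inf
        a = 1.0 - d1 * y1 * y1
        m = d2 * (1.0 - y1 * y1) / a
        return 0.5 * (log(a) + log(1.0 - m * y2 * y2) - log(1.0 - y2 * y2))

    return log_target


def sample_general_ellipsoid(spec: EllipsoidPatchSpec, n: int, seed: int,
                             config: HastingsConfig | None = None) -> SampleBatch:
    """Surface-uniform sampling on any (including triaxial) ellipsoid patch.

    Runs :func:`hastings_chain` on the unnormalized 2-D density ``f_g`` over
    ``D_g`` — inverse transforms are unavailable here because the marginals
    involve elliptic integrals — then maps the chain to planar and surface
    coordinates.  The realized acceptance rate is stored on the batch as
    ``batch.acceptance_rate``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config if config is not None else default_hastings_config(spec, seed=seed)
    y, rate = hastings_chain(_fast_log_fg(spec), cfg, n)
    batch = _batch_from_y(spec, "hastings", cfg.seed, y[:, 0], y[:, 1])
    batch.acceptance_rate = rate  # type: ignore[attr-defined]
    return batch


# ---------------------------------------------------------------------------
# uniformity diagnostics
# ---------------------------------------------------------------------------

@dataclass
class UniformityGrid:
    """Rectangular ``y``-space grid with the true surface area of every cell."""

    y1_edges: np.ndarray
    y2_edges: np.ndarray
    areas: np.ndarray  # (k1, k2) cell surface areas by quadrature

    @property
    def k_bins(self) -> int:
        return self.areas.size


def _near_square_factors(k: int) -> tuple[int, int]:
    best = (1, k)
    for d in range(1, int(math.isqrt(k)) + 1):
        if k % d == 0:
            best = (d, k // d)
    return best


def make_uniformity_grid(spec: EllipsoidPatchSpec, k1: int, k2: int) -> UniformityGrid:
    """Build a ``k1 x k2`` near-equal-area grid on ``D_g`` with exact cell areas.

    Edges are placed at quantiles of the two marginal area profiles (for
    spheres and ellipsoids of revolution the area measure factorizes, so the
    cells are exactly equal-area up to profile-inversion error); each cell's
    true surface area is then computed by 2-D quadrature, so the expected
    counts are exact regardless of the edge placement.
    """
    lo1, hi1 = spec.y1_bounds
    lo2, hi2 = spec.y2_bounds
    # y1 edges: quantiles of the cumulative of the y1 area profile sqrt(1-d1*y1^2)
    d1 = spec.delta1
    if d1 > 0:
        cum = phi(np.linspace(lo1, hi1, 4001), d1)
        grid = np.linspace(lo1, hi1, 4001)
        targets = cum[0] + (cum[-1] - cum[0]) * np.arange(1, k1) / k1
        y1_edges = np.concatenate([[lo1], np.interp(targets, cum, grid), [hi1]])
    else:
        y1_edges = np.linspace(lo1, hi1, k1 + 1)
    # y2 edges: quantiles of the arcsin profile (exact for the separable cases)
    t_lo, t_hi = math.asin(lo2), math.asin(hi2)
    y2_edges = np.sin(np.linspace(t_lo, t_hi, k2 + 1))
    y2_edges[0], y2_edges[-1] = lo2, hi2
    areas = np.empty((k1, k2))
    for i in range(k1):
        for j in range(k2):
            areas[i, j] = patch_area(spec,
                                     y1_bounds=(y1_edges[i], y1_edges[i + 1]),
                                     y2_bounds=(y2_edges[j], y2_edges[j + 1]),
                                     epsrel=1e-9)
    return UniformityGrid(y1_edges=y1_edges, y2_edges=y2_edges, areas=areas)


def uniformity_chi_square(batch: SampleBatch, spec: EllipsoidPatchSpec,
                          k_bins: int, grid: UniformityGrid | None = None
                          ) -> tuple[float, float]:
    """Pearson chi-square test of surface uniformity on a ``y``-space grid.

    Expected counts are ``n * area_cell / area_total`` with areas from
    quadrature; returns ``(statistic, p_value)`` on ``k_bins - 1`` degrees of
    freedom.  A surface-uniform sampler should give a statistic consistent
    with the chi-square law — points must not accumulate anywhere.
    """
    if k_bins < 2:
        raise ValueError("k_bins must be >= 2")
    if batch.n < 10 * k_bins:
        raise ValueError("need at least 10 samples per bin on average")
    if grid is None:
        k1, k2 = _near_square_factors(k_bins)
        grid = make_uniformity_grid(spec, k1, k2)
    elif grid.k_bins != k_bins:
        raise ValueError("supplied grid does not have k_bins cells")
    counts, _, _ = np.histogram2d(batch.y[:, 0], batch.y[:, 1],
                                  bins=[grid.y1_edges, grid.y2_edges])
    expected = batch.n * grid.areas / grid.areas.sum()
    if np.any(expected < 5.0):
        raise ValueError("expected count below 5 in at least one cell; use fewer bins")
    stat = float(np.sum((counts - expected) ** 2 / expected))
    p = float(stats.chi2.sf(stat, df=k_bins - 1))
    return stat, p
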