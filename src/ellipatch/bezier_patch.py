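"""Rational triangular Bézier patches: de Casteljau and Bernstein evaluation.

These are the deterministic comparators to the random samplers: a sphere (or
ellipsoid) octant realized exactly as a degree-4 rational triangular patch and
evaluated on a barycentric lattice.

Multi-indices ``i = (i1, i2, i3)`` with ``|i| = n`` are stored in lexicographic
order of ``(i1, i2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

Index = Tuple[int, int, int]

__all__ = [
    "RationalTriangularPatch", "multi_indices", "de_casteljau", "bernstein_eval",
    "sphere_octant_patch", "ellipsoid_octant_patch", "barycentric_grid",
    "barycentric_points_for_count",
]


def multi_indices(n: int) -> list[Index]:
    """All multi-indices of total degree ``n``, lexicographic in ``(i1, i2)``."""
    return [(i1, i2, n - i1 - i2) for i1 in range(n + 1) for i2 in range(n + 1 - i1)]


def _check_barycentric(u, *, domain: bool = True) -> np.ndarray:
    ua = np.atleast_2d(np.asarray(u, dtype=float))
    if ua.shape[-1] != 3:
        raise ValueError("barycentric coordinates must have three components")
    if np.any(np.abs(ua.sum(axis=-1) - 1.0) > 1e-12):
        raise ValueError("barycentric coordinates must sum to 1")
    if domain and np.any(ua < -1e-12):
        raise ValueError("domain points need nonnegative barycentric coordinates")
    return ua


@dataclass
class RationalTriangularPatch:
    """Degree-``n`` triangular control net ``b_i`` with positive weights ``w_i``."""

    degree: int
    control_points: Dict[Index, np.ndarray]
    weights: Dict[Index, float]

    def __post_init__(self) -> None:
        n = self.degree
        expected = set(multi_indices(n))
        if set(self.control_points) != expected or set(self.weights) != expected:
            raise ValueError(
                f"degree-{n} patch needs exactly the {(n + 1) * (n + 2) // 2} "
                f"multi-indices of total degree {n}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all weights must be strictly positive")
        self.control_points = {i: np.asarray(p, dtype=float)
                               for i, p in self.control_points.items()}

    # arrays in canonical index order, for vectorized evaluation
    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        idx = multi_indices(self.degree)
        b = np.stack([self.control_points[i] for i in idx])
        w = np.array([self.weights[i] for i in idx])
        return b, w

    def evaluate(self, u, algorithm: str = "de_casteljau") -> np.ndarray:
        if algorithm == "de_casteljau":
            return de_casteljau(self, u)
        if algorithm == "bernstein":
            return bernstein_eval(self, u)
        raise ValueError(f"unknown algorithm {algorithm!r}")

    def to_csv(self, path) -> None:
        from . import io as _io
        _io.write_control_net_csv(path, self)


def de_casteljau(patch: RationalTriangularPatch, u) -> np.ndarray:
    """Evaluate by the rational de Casteljau recursion.

    At every level ``r`` the weights and weighted points are recombined:

    ``w_i^r = u*w_{i+e1}^{r-1} + v*w_{i+e2}^{r-1} + w*w_{i+e3}^{r-1}``
    ``b_i^r = (u*w_{i+e1}^{r-1}*b_{i+e1}^{r-1} + v*w_{i+e2}^{r-1}*b_{i+e2}^{r-1}
    + w*w_{i+e3}^{r-1}*b_{i+e3}^{r-1}) / w_i^r``

    with ``b_i^0 = b_i``; after ``n`` levels ``b_0^n(u)`` is the surface point.
    Accepts one barycentric triple or an ``(m, 3)`` array of them.
    """
    ua = _check_barycentric(u)
    single = np.ndim(u) == 1
    m = ua.shape[0]
    n = patch.degree
    uu, vv, ww = ua[:, 0:1], ua[:, 1:2], ua[:, 2:3]
    # level arrays keyed by multi-index: weights (m,), weighted points (m, 3)
    w_lvl = {i: np.full(m, patch.weights[i]) for i in multi_indices(n)}
    b_lvl = {i: np.broadcast_to(patch.control_points[i], (m, 3)).copy()
             for i in multi_indices(n)}
    for r in range(1, n + 1):
        w_new: dict[Index, np.ndarray] = {}
        b_new: dict[Index, np.ndarray] = {}
        for i in multi_indices(n - r):
            i1, i2, i3 = i
            e1, e2, e3 = (i1 + 1, i2, i3), (i1, i2 + 1, i3), (i1, i2, i3 + 1)
            w1, w2, w3 = w_lvl[e1], w_lvl[e2], w_lvl[e3]
            wr = uu[:, 0] * w1 + vv[:, 0] * w2 + ww[:, 0] * w3
            br = (uu * (w1[:, None] * b_lvl[e1]) + vv * (w2[:, None] * b_lvl[e2])
                  + ww * (w3[:, None] * b_lvl[e3])) / wr[:, None]
            w_new[i] = wr
            b_new[i] = br
        w_lvl, b_lvl = w_new, b_new
    out = b_lvl[(0, 0, 0)]
    return out[0] if single else out


def _bernstein_basis(n: int, ua: np.ndarray) -> np.ndarray:
    """Matrix of ``B_i^n(u)`` values, shape (m, n_indices), canonical index order."""
    idx = multi_indices(n)
    coef = np.array([math.factorial(n) // (math.factorial(i1) * math.factorial(i2)
                                           * math.factorial(i3))
                     for i1, i2, i3 in idx], dtype=float)
    i_arr = np.array(idx, dtype=float)  # (k, 3)
    # u^{i1} v^{i2} w^{i3}; 0**0 == 1 under numpy power
    powers = np.prod(ua[:, None, :] ** i_arr[None, :, :], axis=-1)
    return coef[None, :] * powers


def bernstein_eval(patch: RationalTriangularPatch, u) -> np.ndarray:
    """Evaluate through the homogeneous Bernstein form.

    ``b^n(u) = sum_i w_i b_i B_i^n(u) / sum_i w_i B_i^n(u)`` with the multinomial
    basis ``B_i^n(u) = n!/(i1! i2! i3!) u^{i1} v^{i2} w^{i3}``.
    """
    ua = _check_barycentric(u)
    single = np.ndim(u) == 1
    b, w = patch._arrays()
    basis = _bernstein_basis(patch.degree, ua)          # (m, k)
    denom = basis @ w                                   # (m,)
    if np.any(denom <= 0):
        raise ArithmeticError("nonpositive rational denominator (should be impossible "
                              "with positive weights on the domain triangle)")
    num = basis @ (w[:, None] * b)                      # (m, 3)
    out = num / denom[:, None]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# exact octant patches
# ---------------------------------------------------------------------------

def _multinomial(n: int, i: Index) -> int:
    return math.factorial(n) // (math.factorial(i[0]) * math.factorial(i[1])
                                 * math.factorial(i[2]))


def _bernstein_product(f: Dict[Index, float], p: int,
                       g: Dict[Index, float], q: int) -> Dict[Index, float]:
    """Bernstein coefficients of the product of two polynomials given in
    Bernstein form: ``(fg)_k = sum_{i+j=k} C_p(i) C_q(j) / C_{p+q}(k) f_i g_j``."""
    out: Dict[Index, float] = {k: 0.0 for k in multi_indices(p + q)}
    for i, fi in f.items():
        ci = _multinomial(p, i)
        for j, gj in g.items():
            k = (i[0] + j[0], i[1] + j[1], i[2] + j[2])
            out[k] += ci * _multinomial(q, j) / _multinomial(p + q, k) * fi * gj
    return out


def sphere_octant_patch(radius: float = 1.0) -> RationalTriangularPatch:
    """The positive-octant sphere as an exact degree-4 rational triangular patch.

    Construction: the inverse stereographic projection from the south pole,
    ``(x, y) -> (2x, 2y, 1 - x^2 - y^2)/(1 + x^2 + y^2)``, pulls the octant
    back to the quarter disc; a rational *quadratic* triangular patch maps the
    domain triangle onto that quarter disc (two straight edges, one circular
    arc with the classical 90-degree-arc weight ``sqrt(2)/2``).  Composing the
    two — all done on homogeneous Bernstein coefficients via exact product
    formulas — yields a degree-4 rational patch whose every point lies exactly
    on the sphere, with corners at ``(r,0,0)``, ``(0,r,0)``, ``(0,0,r)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    h = math.sqrt(2.0) / 2.0
    # homogeneous quadratic coefficients (X, Y, W) of the triangle -> quarter-disc map
    X = {(2, 0, 0): 1.0, (0, 2, 0): 0.0, (0, 0, 2): 0.0,
         (1, 1, 0): h, (1, 0, 1): 0.5, (0, 1, 1): 0.0}
    Y = {(2, 0, 0): 0.0, (0, 2, 0): 1.0, (0, 0, 2): 0.0,
         (1, 1, 0): h, (1, 0, 1): 0.0, (0, 1, 1): 0.5}
    W = {(2, 0, 0): 1.0, (0, 2, 0): 1.0, (0, 0, 2): 1.0,
         (1, 1, 0): h, (1, 0, 1): 1.0, (0, 1, 1): 1.0}
    XX = _bernstein_product(X, 2, X, 2)
    YY = _bernstein_product(Y, 2, Y, 2)
    WW = _bernstein_product(W, 2, W, 2)
    XW = _bernstein_product(X, 2, W, 2)
    YW = _bernstein_product(Y, 2, W, 2)
    idx4 = multi_indices(4)
    weights: Dict[Index, float] = {}
    control: Dict[Index, np.ndarray] = {}
    for k in idx4:
        den = WW[k] + XX[k] + YY[k]
        weights[k] = den
        control[k] = radius * np.array([2.0 * XW[k], 2.0 * YW[k],
                                        WW[k] - XX[k] - YY[k]]) / den
    return RationalTriangularPatch(degree=4, control_points=control, weights=weights)


def ellipsoid_octant_patch(a1: float, a2: float, a3: float) -> RationalTriangularPatch:
    """Positive octant of the ellipsoid ``(x/a1)^2+(y/a2)^2+(z/a3)^2=1`` of degree 4.

    Anisotropic scaling of the unit-sphere octant's control points (weights
    unchanged) — rational patches commute with affine maps, so every evaluated
    point lies exactly on the ellipsoid.
    """
    if min(a1, a2, a3) <= 0:
        raise ValueError("semiaxes must be positive")
    base = sphere_octant_patch(1.0)
    scale = np.array([a1, a2, a3])
    control = {i: p * scale for i, p in base.control_points.items()}
    return RationalTriangularPatch(degree=4, control_points=control,
                                   weights=dict(base.weights))


# ---------------------------------------------------------------------------
# deterministic parameter lattices
# ---------------------------------------------------------------------------

def barycentric_grid(m: int) -> np.ndarray:
    """The triangular lattice ``{(i/m, j/m, (m-i-j)/m)}``: ``(m+1)(m+2)/2`` points.

    Deterministic lexicographic order in ``(i, j)``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    pts = [(i / m, j / m, (m - i - j) / m)
           for i in range(m + 1) for j in range(m + 1 - i)]
    return np.array(pts)


def barycentric_points_for_count(n: int) -> np.ndarray:
    """Exactly ``n`` deterministic barycentric points.

    Uses the densest triangular lattice with at most ``n`` points and tops it
    up with the leading points of the next-finer lattice (a partial first
    row), so benchmark sizes that are not triangular numbers — such as 50086 —
    are still met exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n < 3:
        return barycentric_grid(1)[:n]
    m = int((math.isqrt(8 * n + 1) - 3) // 2)  # largest m with (m+1)(m+2)/2 <= n
    pts = barycentric_grid(m)
    short = n - pts.shape[0]
    if short:
        extra = barycentric_grid(m + 1)[:short]
        pts = np.vstack([pts, extra])
    return pts
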