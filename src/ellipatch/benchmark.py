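"""Timing harness comparing random and deterministic patch evaluation.

Reproduces the shape of the classic comparison tables — one row per applicable
method, one column per point count ``n in {1035, 10011, 50086}`` (1035 and
10011 are triangular lattice counts, ``m = 44`` and ``m = 140``; non-triangular
counts are met exactly by topping up the lattice) — on the sphere octant and
the ellipsoid-of-revolution octant.  Timings are reported, never asserted:
they are hardware facts, not correctness facts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .bezier_patch import (
    RationalTriangularPatch,
    barycentric_points_for_count,
    bernstein_eval,
    de_casteljau,
    ellipsoid_octant_patch,
    sphere_octant_patch,
)
from .patch_geometry import EllipsoidPatchSpec
from .samplers import (
    build_phi_inverse,
    default_hastings_config,
    sample_general_ellipsoid,
    sample_revolution_ar,
    sample_revolution_inverse,
    sample_sphere_inverse,
)

DEFAULT_NS = (1035, 10011, 50086)


def sphere_octant_spec(radius: float = 1.0) -> EllipsoidPatchSpec:
    """The positive octant of a sphere as a patch spec (alpha, beta in [0, 1])."""
    return EllipsoidPatchSpec(radius, radius, radius, 1.0, 0.0, radius, 0.0)


def revolution_octant_spec(a1: float = 2.0, a23: float = 1.0) -> EllipsoidPatchSpec:
    """The positive octant of an ellipsoid of revolution as a patch spec."""
    return EllipsoidPatchSpec(a1, a23, a23, 1.0, 0.0, a1, 0.0)


@dataclass
class BenchmarkTable:
    """Rows = methods, columns = point counts; cells = seconds (median of repeats)."""

    shape: str
    ns: tuple[int, ...]
    methods: list[str]
    times: np.ndarray  # (len(methods), len(ns))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("method," + ",".join(f"n={n}" for n in self.ns) + "\n")
            for i, m in enumerate(self.methods):
                fh.write(m + "," + ",".join(f"{t:.6g}" for t in self.times[i]) + "\n")

    def format(self) -> str:
        width = max(len(m) for m in self.methods) + 2
        lines = ["".join([" " * width] + [f"n={n}".rjust(12) for n in self.ns])]
        for i, m in enumerate(self.methods):
            lines.append(m.ljust(width) + "".join(f"{t:12.6f}" for t in self.times[i]))
        return "\n".join(lines)


def _time_call(fn, repeats: int) -> float:
    fn()  # warm-up (JIT-free, but primes caches and lazy tables)
    samples = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        fn()
        samples.append(time.perf_counter() - t0)
    return float(np.median(samples))


def _deterministic_rows(patch: RationalTriangularPatch, ns, repeats, rows, times) -> None:
    for n in ns:
        pts = barycentric_points_for_count(n)
        times.setdefault("bernstein", []).append(
            _time_call(lambda: bernstein_eval(patch, pts), repeats))
        times.setdefault("de_casteljau", []).append(
            _time_call(lambda: de_casteljau(patch, pts), repeats))
    rows.extend(["bernstein", "de_casteljau"])


def benchmark_sphere(ns=DEFAULT_NS, repeats: int = 7, seed: int = 0) -> BenchmarkTable:
    """Sphere octant: inverse transform vs the two deterministic evaluators."""
    spec = sphere_octant_spec()
    patch = sphere_octant_patch()
    rows: list[str] = ["inverse_transform"]
    times: dict[str, list[float]] = {}
    for n in ns:
        times.setdefault("inverse_transform", []).append(
            _time_call(lambda: sample_sphere_inverse(spec, n, seed), repeats))
    _deterministic_rows(patch, ns, repeats, rows, times)
    return BenchmarkTable("sphere_octant", tuple(ns), rows,
                          np.array([times[m] for m in rows]))


def benchmark_revolution(ns=DEFAULT_NS, repeats: int = 7, seed: int = 0,
                         a1: float = 2.0) -> BenchmarkTable:
    """Ellipsoid-of-revolution octant: phi-inverse, AR, Hastings and the
    deterministic evaluators."""
    spec = revolution_octant_spec(a1=a1)
    patch = ellipsoid_octant_patch(a1, 1.0, 1.0)
    transform = build_phi_inverse()  # table built once, outside the timed region
    rows: list[str] = ["phi_inverse", "acceptance_rejection", "hastings"]
    times: dict[str, list[float]] = {}
    for n in ns:
        times.setdefault("phi_inverse", []).append(
            _time_call(lambda: sample_revolution_inverse(spec, n, seed, transform),
                       repeats))
        times.setdefault("acceptance_rejection", []).append(
            _time_call(lambda: sample_revolution_ar(spec, n, seed), repeats))
        cfg = default_hastings_config(spec, seed=seed)
        times.setdefault("hastings", []).append(
            _time_call(lambda: sample_general_ellipsoid(spec, n, seed, cfg), repeats))
    _deterministic_rows(patch, ns, repeats, rows, times)
    return BenchmarkTable("revolution_octant", tuple(ns), rows,
                          np.array([times[m] for m in rows]))
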