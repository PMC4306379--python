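"""Patch domain, surface graph, densities, change of variables, area."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from ellipatch import (
    EllipsoidPatchSpec,
    density_f,
    density_fg,
    map_g,
    map_g_inverse,
    patch_area,
    shape_deltas,
    surface_point,
)
from ellipatch.errors import DomainError, SpecError

from conftest import random_interior_y


# -- spec validation and shape parameters -----------------------------------

@pytest.mark.parametrize("kwargs,msg", [
    (dict(a1=1, a2=2, a3=1, alpha1=1, alpha2=-1, beta1=1, beta2=-1), "a1 >= a2"),
    (dict(a1=1, a2=1, a3=0, alpha1=1, alpha2=-1, beta1=1, beta2=-1), "positive"),
    (dict(a1=1, a2=1, a3=1, alpha1=2, alpha2=-1, beta1=1, beta2=-1), "alpha1"),
    (dict(a1=1, a2=1, a3=1, alpha1=1, alpha2=-1, beta1=2, beta2=-1), "beta1"),
    (dict(a1=1, a2=1, a3=1, alpha1=-0.5, alpha2=0.5, beta1=1, beta2=-1), "alpha2 < alpha1"),
    (dict(a1=1, a2=1, a3=1, alpha1=1, alpha2=-1, beta1=-1, beta2=1), "beta2 < beta1"),
])
def test_invalid_specs_name_the_violated_invariant(kwargs, msg):
    with pytest.raises(SpecError, match=msg):
        EllipsoidPatchSpec(**kwargs)


@pytest.mark.parametrize("axes,expected", [
    ((1, 1, 1), (0.0, 0.0)),
    ((2, 1, 1), (0.75, 0.0)),
    ((3, 2, 1), (8 / 9, 3 / 4)),
])
def test_shape_deltas_by_direct_substitution(axes, expected):
    a1, a2, a3 = axes
    spec = EllipsoidPatchSpec(a1, a2, a3, 1.0, -1.0, a1, -a1)
    params = shape_deltas(spec)
    assert params.delta1 == pytest.approx(expected[0], abs=1e-15)
    assert params.delta2 == pytest.approx(expected[1], abs=1e-15)
    assert params.kappa is None  # lazy unless requested


def test_shape_deltas_kappa_is_reciprocal_area(sphere_hemisphere):
    params = shape_deltas(sphere_hemisphere, with_kappa=True)
    assert params.kappa == pytest.approx(1.0 / (2 * math.pi), rel=1e-9)


@st.composite
def patch_specs(draw):
    a1 = draw(st.floats(0.5, 5.0))
    a2 = draw(st.floats(0.25, 1.0)) * a1
    a3 = draw(st.floats(0.25, 1.0)) * a2
    alpha2 = draw(st.floats(-1.0, 0.8))
    alpha1 = draw(st.floats(alpha2 + 0.1, 1.0))
    beta2 = draw(st.floats(-1.0, 0.8)) * a1
    beta1 = draw(st.floats(beta2 / a1 + 0.1, 1.0)) * a1
    return EllipsoidPatchSpec(a1, a2, a3, alpha1, alpha2, beta1, beta2)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(patch_specs())
def test_delta_ordering_invariant(spec):
    """1 > delta1 >= delta2 >= 0 for every valid spec."""
    assert 1 > spec.delta1 >= spec.delta2 >= 0


def test_shape_flags():
    assert EllipsoidPatchSpec(1, 1, 1, 1, -1, 1, -1).is_sphere
    rev = EllipsoidPatchSpec(2, 1, 1, 1, -1, 2, -2)
    assert rev.is_revolution and not rev.is_sphere
    tri = EllipsoidPatchSpec(3, 2, 1, 1, -1, 3, -3)
    assert not tri.is_revolution and not tri.is_sphere


# -- surface graph -----------------------------------------------------------

def test_surface_point_examples(sphere_hemisphere):
    assert surface_point(sphere_hemisphere, 0.0, 0.0) == pytest.approx((0, 0, 1))
    # equator: radicand exactly 0
    assert surface_point(sphere_hemisphere, 1.0, 0.0) == pytest.approx((1, 0, 0))
    assert surface_point(sphere_hemisphere, 0.5, 0.5) == pytest.approx(
        (0.5, 0.5, math.sqrt(0.5)))


def test_surface_point_outside_domain_raises(sphere_octant):
    with pytest.raises(DomainError):
        surface_point(sphere_octant, -0.5, 0.2)  # x1 below beta2=0
    with pytest.raises(DomainError):
        surface_point(sphere_octant, 0.9, 0.9)   # off the ellipse


# -- change of variables -----------------------------------------------------

def test_map_g_inverse_examples(revolution_patch):
    assert map_g_inverse(revolution_patch, 0.0, 0.0) == pytest.approx((0.0, 0.0))
    x1, x2 = map_g_inverse(revolution_patch, 0.0, 0.7)
    assert (x1, x2) == pytest.approx((0.0, revolution_patch.a2 * 0.7))


def test_map_g_round_trip_bijection(triaxial_patch):
    """g and g^{-1} are mutually inverse on D <-> D_g to 1e-12."""
    y1, y2 = random_interior_y(triaxial_patch, 1000, seed=42, margin=0.0)
    x1, x2 = map_g_inverse(triaxial_patch, y1, y2)
    y1b, y2b = map_g(triaxial_patch, x1, x2)
    np.testing.assert_allclose(y1b, y1, atol=1e-12)
    np.testing.assert_allclose(y2b, y2, atol=1e-12)


def test_map_g_inverse_outside_rectangle_raises(sphere_octant):
    with pytest.raises(DomainError):
        map_g_inverse(sphere_octant, -0.5, 0.5)


# -- densities ---------------------------------------------------------------

def test_density_f_center_and_sphere_form(triaxial_patch, sphere_hemisphere):
    assert density_f(triaxial_patch, 0.0, 0.0) == pytest.approx(1.0)
    # sphere: f = 1/sqrt(1 - (x1/a1)^2 - (x2/a2)^2) unnormalized
    x1, x2 = 0.3, 0.4
    expected = 1.0 / math.sqrt(1 - x1 ** 2 - x2 ** 2)
    assert density_f(sphere_hemisphere, x1, x2) == pytest.approx(expected, rel=1e-12)


def test_density_f_equator_singularity_raises(sphere_hemisphere):
    with pytest.raises(DomainError):
        density_f(sphere_hemisphere, 1.0, 0.0)


def test_density_f_minimum_at_center_and_at_least_one(triaxial_patch):
    y1, y2 = random_interior_y(triaxial_patch, 400, seed=3)
    x1, x2 = map_g_inverse(triaxial_patch, y1, y2)
    vals = density_f(triaxial_patch, x1, x2)
    assert np.all(vals >= 1.0 - 1e-12)


def test_normalized_density_integrates_to_one():
    """Quadrature of the normalized f over D equals 1 (interior patch)."""
    spec = EllipsoidPatchSpec(2, 1, 1, 0.5, -0.5, 1.0, -1.0)
    kappa = 1.0 / patch_area(spec)

    def f(x2, x1):
        return density_f(spec, x1, x2, normalized=True, kappa=kappa)

    def lo(x1):
        return spec.alpha2 * spec.a2 * math.sqrt(1 - (x1 / spec.a1) ** 2)

    def hi(x1):
        return spec.alpha1 * spec.a2 * math.sqrt(1 - (x1 / spec.a1) ** 2)

    total, _ = integrate.dblquad(f, spec.beta2, spec.beta1, lo, hi, epsrel=1e-9)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_density_fg_reduces_to_sphere_and_revolution_forms(sphere_hemisphere,
                                                           revolution_patch):
    # sphere: f_g = a1^2 / sqrt(1 - y2^2)
    y1, y2 = 0.3, 0.6
    assert density_fg(sphere_hemisphere, y1, y2) == pytest.approx(
        1.0 / math.sqrt(1 - y2 ** 2), rel=1e-12)
    # revolution: f_g = a1*a2*sqrt(1 - d1*y1^2)/sqrt(1 - y2^2)
    d1 = revolution_patch.delta1
    expected = 2.0 * math.sqrt(1 - d1 * y1 ** 2) / math.sqrt(1 - y2 ** 2)
    assert density_fg(revolution_patch, y1, y2) == pytest.approx(expected, rel=1e-12)


def test_density_fg_change_of_variables_consistency(triaxial_patch):
    """f_g(y) = f(g^{-1}(y)) * |J g^{-1}(y)| with the Jacobian from central
    finite differences (independent oracle for the analytic form)."""
    spec = triaxial_patch
    y1, y2 = random_interior_y(spec, 1000, seed=11)
    h = 3e-6

    def ginv(a, b):
        return np.stack(map_g_inverse(spec, a, b))

    j11, j21 = (ginv(y1 + h, y2) - ginv(y1 - h, y2)) / (2 * h)
    j12, j22 = (ginv(y1, y2 + h) - ginv(y1, y2 - h)) / (2 * h)
    det = np.abs(j11 * j22 - j12 * j21)
    x1, x2 = map_g_inverse(spec, y1, y2)
    lhs = density_fg(spec, y1, y2)
    rhs = density_f(spec, x1, x2) * det
    np.testing.assert_allclose(lhs, rhs, rtol=1e-9)


def test_density_fg_rejects_y2_at_one(sphere_hemisphere):
    with pytest.raises(DomainError):
        density_fg(sphere_hemisphere, 0.0, 1.0)


# -- area --------------------------------------------------------------------

def test_patch_area_hemisphere_and_octant(sphere_hemisphere, sphere_octant):
    assert patch_area(sphere_hemisphere) == pytest.approx(2 * math.pi, rel=1e-9)
    assert patch_area(sphere_octant) == pytest.approx(math.pi / 2, rel=1e-9)


def test_patch_area_matches_spheroid_closed_form(revolution_patch):
    """Half the prolate-spheroid area: pi*a^2 + pi*a*c/e * arcsin(e)... the
    classical closed form, an oracle fully independent of the quadrature."""
    a, c = 1.0, 2.0  # transverse, polar semiaxes
    e = math.sqrt(1 - (a / c) ** 2)
    half_area = math.pi * a * a + math.pi * a * c / e * math.asin(e)
    assert patch_area(revolution_patch) == pytest.approx(half_area, rel=1e-6)


def test_patch_area_additive_under_beta_split(triaxial_patch):
    s = triaxial_patch
    left = EllipsoidPatchSpec(s.a1, s.a2, s.a3, s.alpha1, s.alpha2, 0.0, s.beta2)
    right = EllipsoidPatchSpec(s.a1, s.a2, s.a3, s.alpha1, s.alpha2, s.beta1, 0.0)
    assert patch_area(left) + patch_area(right) == pytest.approx(
        patch_area(s), rel=1e-8)


# -- serialization -----------------------------------------------------------

def test_config_round_trip_is_bit_exact():
    spec = EllipsoidPatchSpec(2.123456789012345, 1.1, 1.0999999999999999,
                              0.123456789012345, -0.9, 1.9999999999999998, -2.0)
    again = EllipsoidPatchSpec.from_config(spec.to_config())
    for name in EllipsoidPatchSpec._FIELDS:
        assert getattr(again, name) == getattr(spec, name)
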