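"""Random generators: inverse transform, acceptance-rejection, Hastings."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from ellipatch import EllipsoidPatchSpec
from ellipatch.errors import DomainError, ShapeBranchError
from ellipatch.samplers import (
    SampleBatch,
    ar_envelope,
    build_phi_inverse,
    default_hastings_config,
    hastings_chain,
    make_uniformity_grid,
    marginal_cdf_y1,
    marginal_cdf_y2,
    phi,
    sample_ar_y1,
    sample_general_ellipsoid,
    sample_revolution_ar,
    sample_revolution_inverse,
    sample_sphere_inverse,
    semicircular_endpoints,
    uniformity_chi_square,
)

#: thinning used whenever chain output feeds an independence-assuming test
#: (KS, chi-square); about three times the measured integrated autocorrelation
#: time of the default random-walk chain.
CHAIN_THIN = 80


# -- phi and its tabulated inverse ------------------------------------------

def test_phi_closed_form_values():
    assert phi(0.0, 0.37) == 0.0
    assert phi(1.0, 1.0) == pytest.approx(math.pi / 4, abs=1e-15)


def test_phi_matches_quadrature_oracle():
    """phi(t; d) equals the integral of sqrt(1 - d*s^2) from 0 to t."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        d = rng.uniform(0.05, 1.0)
        t = rng.uniform(-1.0, 1.0) / math.sqrt(d)
        ref, _ = integrate.quad(lambda s: math.sqrt(1 - d * s * s), 0.0, t,
                                epsabs=1e-14)
        assert phi(t, d) == pytest.approx(ref, abs=1e-12)


def test_phi_domain_and_branch_errors():
    with pytest.raises(ShapeBranchError):
        phi(0.5, 0.0)
    with pytest.raises(DomainError):
        phi(1.5, 1.0)


def test_phi_inverse_interpolates_knots_and_origin(phi_inverse_200):
    tr = phi_inverse_200
    assert tr(0.0) == pytest.approx(0.0, abs=1e-12)       # odd symmetry
    assert tr(math.pi / 4) == pytest.approx(1.0, abs=1e-12)  # phi(1;1)=pi/4 knot
    assert tr(-math.pi / 4) == pytest.approx(-1.0, abs=1e-12)


def test_phi_inverse_residual_bound_and_monotone_accuracy(phi_inverse_200):
    """Max |phi(interp(u);1) - u| <= 1e-6 at 200 knots, decreasing with knots."""
    assert phi_inverse_200.max_residual(100_000) <= 1e-6
    residuals = [build_phi_inverse(k).max_residual(20_000)
                 for k in (50, 100, 200, 400)]
    assert all(a > b for a, b in zip(residuals, residuals[1:]))


def test_phi_inverse_is_monotone(phi_inverse_200):
    u = np.linspace(-math.pi / 4, math.pi / 4, 5000)
    v = phi_inverse_200(u)
    assert np.all(np.diff(v) >= 0)


def test_phi_inverse_rejects_tiny_tables():
    with pytest.raises(ValueError):
        build_phi_inverse(3)


# -- inverse-transform samplers ---------------------------------------------

def test_sphere_sampler_branch_guard(revolution_patch):
    with pytest.raises(ShapeBranchError):
        sample_sphere_inverse(revolution_patch, 10, 0)


def test_revolution_sampler_branch_guards(sphere_hemisphere, triaxial_patch):
    with pytest.raises(ShapeBranchError):
        sample_revolution_inverse(sphere_hemisphere, 10, 0)
    with pytest.raises(ShapeBranchError):
        sample_revolution_inverse(triaxial_patch, 10, 0)


def test_marginal_cdf_endpoints(sphere_octant, revolution_patch):
    """The inverse-CDF endpoints: U=0 and U=1 map to the domain bounds."""
    for spec in (sphere_octant, revolution_patch):
        lo1, hi1 = spec.y1_bounds
        assert marginal_cdf_y1(spec, lo1) == pytest.approx(0.0, abs=1e-12)
        assert marginal_cdf_y1(spec, hi1) == pytest.approx(1.0, abs=1e-12)
        lo2, hi2 = spec.y2_bounds
        assert marginal_cdf_y2(spec, lo2) == pytest.approx(0.0, abs=1e-12)
        assert marginal_cdf_y2(spec, hi2) == pytest.approx(1.0, abs=1e-12)


def test_semicircular_endpoints_scaling(revolution_patch):
    r1, r2 = semicircular_endpoints(revolution_patch)
    rd = math.sqrt(revolution_patch.delta1)
    assert r1 == pytest.approx(rd * revolution_patch.beta1 / revolution_patch.a1)
    assert r2 == pytest.approx(rd * revolution_patch.beta2 / revolution_patch.a1)
    assert -1 <= r2 < r1 <= 1


def test_batches_are_reproducible_and_on_surface(sphere_octant, revolution_patch,
                                                 triaxial_patch):
    """Fixed seed => bit-identical batches; all points on the ellipsoid."""
    for spec, sampler in ((sphere_octant, sample_sphere_inverse),
                          (revolution_patch, sample_revolution_inverse),
                          (triaxial_patch, sample_general_ellipsoid)):
        a = sampler(spec, 2000, 123)
        b = sampler(spec, 2000, 123)
        assert np.array_equal(a.points, b.points)
        assert a.quadric_residual(spec) <= 1e-10
        assert a.n == 2000


def test_inverse_marginals_match_analytic_cdfs(sphere_octant, revolution_patch):
    """One-sample KS of each marginal against its analytic CDF."""
    for spec, sampler in ((sphere_octant, sample_sphere_inverse),
                          (revolution_patch, sample_revolution_inverse)):
        batch = sampler(spec, 50_000, 17)
        p1 = stats.kstest(batch.y[:, 0], lambda y: marginal_cdf_y1(spec, y)).pvalue
        p2 = stats.kstest(batch.y[:, 1], lambda y: marginal_cdf_y2(spec, y)).pvalue
        assert p1 > 0.001 and p2 > 0.001


# -- acceptance-rejection ----------------------------------------------------

def test_ar_sphere_limit_is_a_branch_error(sphere_hemisphere):
    # uniform marginal: AR is pointless (c=1, efficiency 1), callers are redirected
    with pytest.raises(ShapeBranchError):
        sample_ar_y1(sphere_hemisphere, 10, 0)


def test_ar_envelope_constant_interior_and_one_sided():
    rev = EllipsoidPatchSpec(2, 1, 1, 1, -1, 2, -2)
    c, f_star, y_star = ar_envelope(rev)
    d1 = rev.delta1
    dphi = phi(1.0, d1) - phi(-1.0, d1)
    assert y_star == 0.0
    assert f_star == pytest.approx(1.0 / dphi, rel=1e-12)
    assert c == pytest.approx(2.0 / dphi, rel=1e-12)
    # interval not containing 0: maximum at the endpoint closer to zero
    one_sided = EllipsoidPatchSpec(2, 1, 1, 1, -1, 2.0, 0.5)
    _, f_star2, y_star2 = ar_envelope(one_sided)
    assert y_star2 == pytest.approx(0.25)
    assert f_star2 > 0


def test_ar_acceptance_rate_matches_inverse_envelope_constant(revolution_patch):
    """Empirical acceptance rate within the 99% binomial CI of 1/c."""
    samples, ar = sample_ar_y1(revolution_patch, 100_000, 21)
    assert ar.n_proposed >= 100_000
    p = 1.0 / ar.c
    half = 2.576 * math.sqrt(p * (1 - p) / ar.n_proposed)
    assert abs(ar.acceptance_rate - p) <= half
    assert samples.shape == (100_000,)


def test_ar_samples_match_analytic_cdf(revolution_patch):
    samples, _ = sample_ar_y1(revolution_patch, 20_000, 22)
    p = stats.kstest(samples, lambda y: marginal_cdf_y1(revolution_patch, y)).pvalue
    assert p > 0.001


def test_ar_full_batch_lies_on_surface(revolution_patch):
    batch, ar = sample_revolution_ar(revolution_patch, 5000, 3)
    assert batch.method == "acceptance_rejection"
    assert batch.quadric_residual(revolution_patch) <= 1e-10
    assert ar.n_accepted == 5000


# -- Hastings ----------------------------------------------------------------

def test_hastings_accepts_everything_on_constant_target():
    cfg = default_hastings_config(
        EllipsoidPatchSpec(1, 1, 1, 1, -1, 1, -1), seed=4, burn_in=100)

    def log_const(y1, y2):
        return 0.0 if (-1 < y1 < 1 and -1 < y2 < 1) else -np.inf

    samples, rate = hastings_chain(log_const, cfg, 2000)
    # every in-box proposal is accepted; rejections are only out-of-box moves
    inside = np.all((samples > -1) & (samples < 1), axis=1)
    assert inside.all()
    assert rate > 0.5


def test_hastings_requires_finite_start(sphere_hemisphere):
    cfg = default_hastings_config(sphere_hemisphere, seed=0, x0=(5.0, 0.0))

    def log_target(y1, y2):
        return 0.0 if abs(y1) < 1 else -np.inf

    with pytest.raises(ValueError):
        hastings_chain(log_target, cfg, 10)


def test_hastings_agrees_with_revolution_inverse(revolution_patch):
    """Two-sample KS per marginal between the chain and the exact sampler."""
    exact = sample_revolution_inverse(revolution_patch, 20_000, 31)
    cfg = default_hastings_config(revolution_patch, seed=32, thin=CHAIN_THIN)
    chain = sample_general_ellipsoid(revolution_patch, 20_000, 32, cfg)
    for k in range(2):
        p = stats.ks_2samp(exact.y[:, k], chain.y[:, k]).pvalue
        assert p > 0.001


def test_hastings_degenerates_to_sphere_sampler(sphere_octant):
    exact = sample_sphere_inverse(sphere_octant, 20_000, 41)
    cfg = default_hastings_config(sphere_octant, seed=42, thin=CHAIN_THIN)
    chain = sample_general_ellipsoid(sphere_octant, 20_000, 42, cfg)
    for k in range(2):
        p = stats.ks_2samp(exact.y[:, k], chain.y[:, k]).pvalue
        assert p > 0.001


def test_cross_method_agreement_inverse_vs_ar(revolution_patch):
    inv = sample_revolution_inverse(revolution_patch, 20_000, 51)
    arb, _ = sample_revolution_ar(revolution_patch, 20_000, 52)
    for k in range(2):
        p = stats.ks_2samp(inv.y[:, k], arb.y[:, k]).pvalue
        assert p > 0.001


# -- chi-square uniformity diagnostic ----------------------------------------

def _fake_batch(y1, y2):
    y = np.column_stack([y1, y2])
    return SampleBatch(method="test", seed=0, y=y, x=y.copy(),
                       points=np.zeros((len(y1), 3)))


def test_chi_square_zero_for_perfectly_proportional_counts(sphere_octant):
    grid = make_uniformity_grid(sphere_octant, 2, 2)
    c1 = 0.5 * (grid.y1_edges[:-1] + grid.y1_edges[1:])
    c2 = 0.5 * (grid.y2_edges[:-1] + grid.y2_edges[1:])
    reps = 100  # equal-area cells: equal counts are exactly proportional
    y1 = np.repeat([c1[0], c1[0], c1[1], c1[1]], reps)
    y2 = np.repeat([c2[0], c2[1], c2[0], c2[1]], reps)
    stat, p = uniformity_chi_square(_fake_batch(y1, y2), sphere_octant, 4, grid=grid)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


def test_chi_square_all_mass_in_one_cell_is_n_times_k_minus_one(sphere_octant):
    grid = make_uniformity_grid(sphere_octant, 2, 2)
    n = 400
    y1 = np.full(n, 0.5 * (grid.y1_edges[0] + grid.y1_edges[1]))
    y2 = np.full(n, 0.5 * (grid.y2_edges[0] + grid.y2_edges[1]))
    stat, _ = uniformity_chi_square(_fake_batch(y1, y2), sphere_octant, 4, grid=grid)
    assert stat == pytest.approx(n * 3, rel=1e-6)


def test_chi_square_guards(sphere_octant):
    batch = sample_sphere_inverse(sphere_octant, 100, 0)
    with pytest.raises(ValueError):
        uniformity_chi_square(batch, sphere_octant, 50)  # < 10 samples/bin


def test_chi_square_statistic_mean_matches_dof(sphere_octant):
    """Mean Pearson statistic over 200 seeded runs within 3 SE of its dof."""
    grid = make_uniformity_grid(sphere_octant, 5, 10)
    stats_ = [uniformity_chi_square(sample_sphere_inverse(sphere_octant, 10_000, s),
                                    sphere_octant, 50, grid=grid)[0]
              for s in range(200)]
    dof = 49
    se = math.sqrt(2 * dof / 200)
    assert abs(np.mean(stats_) - dof) <= 3 * se
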