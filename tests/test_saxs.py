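"""Scattering form factors, Guinier analysis, P(r) inversion and MW."""

import numpy as np
import pytest

import dimerstate as ds
from dimerstate import saxs
from dimerstate.exceptions import FitError


def test_sphere_form_factor_matches_closed_form():
    curve = ds.simulate_saxs_curve("sphere", {"radius": 10.0}, noise=0.0)
    q = curve.q
    x = q * 10.0
    expected = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
    assert np.max(np.abs(curve.I / curve.I[0] - expected / expected[0])) < 1e-10


def test_sphere_guinier_radius_is_sqrt_three_fifths_R():
    curve = ds.simulate_saxs_curve("sphere", {"radius": 10.0}, noise=0.0)
    g = saxs.guinier_fit(curve)
    assert g["rg"] == pytest.approx(np.sqrt(3.0 / 5.0) * 10.0, rel=0.02)


def test_exact_guinier_form_recovered():
    q = np.linspace(0.01, 0.04, 60)
    I = 2.0 * np.exp(-(q**2) * 30.0**2 / 3.0)
    est = saxs.GuinierModel().fit(q, I, sigma=0.001 * I)
    assert est.rg_ == pytest.approx(30.0, abs=0.1)
    assert est.i0_ == pytest.approx(2.0, rel=1e-3)


def test_guinier_rejects_increasing_low_q():
    q = np.linspace(0.01, 0.1, 50)
    I = np.exp(+(q**2) * 100.0)  # aggregation-like upturn
    with pytest.raises(FitError, match="slope"):
        saxs.GuinierModel().fit(q, I, sigma=0.01 * I)


def test_debye_vectorized_matches_double_loop_oracle(rng):
    coords = rng.uniform(-20, 20, size=(60, 3))
    q = np.linspace(0.02, 0.3, 20)
    fast = saxs.debye_intensity(q, coords)
    slow = saxs.debye_intensity_direct(q, coords)
    assert np.max(np.abs(fast - slow)) < 1e-8


def test_dumbbell_beads_match_direct_debye_sum():
    beads = saxs.dumbbell_beads(8.0, 30.0, spacing=6.0)
    assert beads.shape[0] <= 200
    q = np.linspace(0.02, 0.3, 15)
    assert np.max(np.abs(saxs.debye_intensity(q, beads) - saxs.debye_intensity_direct(q, beads))) < 1e-8


def test_bead_body_rg_matches_analytic_ellipsoid():
    a, b = 58.5, 33.8
    beads = saxs.ellipsoid_beads(a, b, b)
    assert saxs.body_rg(beads) == pytest.approx(np.sqrt((a**2 + 2 * b**2) / 5.0), rel=0.005)


# ------------------------------------------------------------------ P(r)

@pytest.fixture(scope="module")
def sphere_curve():
    # small sphere measured to q*R ~ 6, the resolution a 10 A particle needs
    q = np.linspace(0.01, 0.6, 300)
    return ds.simulate_saxs_curve("sphere", {"radius": 10.0}, noise=0.0, q=q)


def test_sphere_pr_matches_closed_form(sphere_curve):
    pr = saxs.ift_pr(sphere_curve, 20.0)
    exact = saxs.sphere_pr(pr.r, 10.0)
    est = pr.p / np.trapezoid(pr.p, pr.r)
    rms = np.sqrt(np.mean((est - exact) ** 2)) / exact.max()
    assert rms < 0.02


def test_pr_endpoints_pinned_to_zero(sphere_curve):
    pr = saxs.ift_pr(sphere_curve, 20.0)
    assert pr.p[0] == 0.0 and pr.p[-1] == 0.0
    assert np.trapezoid(pr.p, pr.r) > 0


def test_rg_from_pr_moments_agrees_with_guinier(sphere_curve):
    pr = saxs.ift_pr(sphere_curve, 20.0)
    g = saxs.guinier_fit(sphere_curve)
    assert pr.rg == pytest.approx(g["rg"], rel=0.03)


def test_sphere_dmax_scan_finds_diameter(sphere_curve):
    best, profile = saxs.scan_dmax(sphere_curve, [15.0, 20.0, 25.0])
    assert best == 20.0
    assert len(profile) == 3


def test_dmax_scan_deterministic(sphere_curve):
    a = saxs.scan_dmax(sphere_curve, [15.0, 20.0, 25.0])
    b = saxs.scan_dmax(sphere_curve, [15.0, 20.0, 25.0])
    assert a[0] == b[0]
    assert all(x["score"] == y["score"] for x, y in zip(a[1], b[1]))


def test_forward_model_consistency_on_noisy_curve():
    curve = ds.simulate_saxs_curve("sphere", {"radius": 30.0}, noise=0.01, seed=3)
    pr = saxs.ift_pr(curve, 60.0)
    assert 0.5 < pr.chi2_dof < 2.0


def test_regularized_solution_approaches_least_squares_as_alpha_vanishes():
    q = np.linspace(0.02, 0.5, 120)
    curve = ds.simulate_saxs_curve("sphere", {"radius": 10.0}, noise=0.0, q=q)
    p_small = saxs.ift_pr(curve, 20.0, alpha=1e-12, n_r=41).p
    p_tiny = saxs.ift_pr(curve, 20.0, alpha=1e-14, n_r=41).p
    assert np.max(np.abs(p_small - p_tiny)) < 1e-3 * np.max(np.abs(p_tiny))


def test_rg_and_dmax_increase_when_dumbbell_elongates():
    rgs, dmaxs = [], []
    for sep in (20.0, 40.0, 60.0):
        curve = ds.simulate_saxs_curve("dumbbell", {"radius": 15.0, "separation": sep}, noise=0.0)
        rgs.append(saxs.guinier_fit(curve)["rg"])
        true_d = sep + 30.0
        best, _ = saxs.scan_dmax(curve, [true_d - 10, true_d, true_d + 10])
        dmaxs.append(best)
    assert rgs[0] < rgs[1] < rgs[2]
    assert dmaxs[0] < dmaxs[1] < dmaxs[2]


# -------------------------------------------------------------------- MW

@pytest.fixture(scope="module")
def wide_sphere():
    q = np.linspace(0.005, 1.5, 600)
    return ds.simulate_saxs_curve("sphere", {"radius": 30.0}, noise=0.0, q=q)


def _truncated(curve, qmax=0.35):
    keep = curve.q <= qmax
    return saxs.SaxsCurve(curve.q[keep], curve.I[keep], curve.sigma[keep])


def test_porod_volume_within_5_percent_of_sphere(wide_sphere):
    pr = saxs.ift_pr(_truncated(wide_sphere), 60.0)
    mw = saxs.mw_estimate(wide_sphere, pr)
    V = 4.0 / 3.0 * np.pi * 30.0**3
    assert mw["volume_A3"] == pytest.approx(V, rel=0.05)
    assert not mw["flagged_inconsistent"]


def test_mw_scales_linearly_with_forward_intensity(wide_sphere):
    q = wide_sphere.q
    double = ds.simulate_saxs_curve("sphere", {"radius": 30.0}, noise=0.0, q=q, I0=2.0)
    pr1 = saxs.ift_pr(_truncated(wide_sphere), 60.0)
    pr2 = saxs.ift_pr(_truncated(double), 60.0)
    mw1 = saxs.mw_estimate(wide_sphere, pr1)
    mw2 = saxs.mw_estimate(double, pr2)
    # V = 2 pi^2 I0/Q is intensity-scale invariant; MW follows the shape
    assert mw2["mw_kda"] == pytest.approx(mw1["mw_kda"], rel=0.01)
    assert mw2["i0_pr"] == pytest.approx(2.0 * mw1["i0_pr"], rel=0.02)


def test_concentration_mismatch_flagged(wide_sphere):
    pr = saxs.ift_pr(_truncated(wide_sphere), 60.0)
    doubled = saxs.SaxsCurve(wide_sphere.q, 2.0 * wide_sphere.I, wide_sphere.sigma)
    mw = saxs.mw_estimate(doubled, pr)  # curve rescaled, P(r) reference kept
    assert mw["flagged_inconsistent"]
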