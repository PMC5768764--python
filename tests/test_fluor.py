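"""Cauchy-profile EM, auto-fluorescence, decay and error-profile estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmtrack.fluor import (autofluor_cell, autofluor_population, column_sums,
                           correct_fluor, fit_cauchy_profile, fit_decay,
                           gfp_error_profile, glucose_windows, profile_loglik)
from mmtrack.simdata import make_profile


def test_column_sums_shape_and_zero_image():
    assert np.array_equal(column_sums(np.zeros((7, 100))), np.zeros(100))
    img = np.arange(12, dtype=float).reshape(3, 4)
    assert np.array_equal(column_sums(img), img.sum(axis=0))


def test_em_recovers_noiseless_parameters():
    c = make_profile(A=1000, B=200, i_mid=51, w=5.5)
    f = fit_cauchy_profile(c)
    assert f.converged
    assert f.A == pytest.approx(1000, rel=5e-3)
    assert f.B == pytest.approx(200, rel=5e-3)
    assert f.i_mid == pytest.approx(51, abs=0.25)
    assert f.w == pytest.approx(5.5, rel=5e-3)


def test_em_constant_profile_goes_to_background():
    f = fit_cauchy_profile(np.full(100, 321.0))
    assert f.B == pytest.approx(321.0, rel=1e-3)
    assert f.A < 1.0


def test_em_translation_covariance():
    """Shifting the profile by k columns shifts i_mid by k, nothing else."""
    base = fit_cauchy_profile(make_profile(A=800, B=150, i_mid=40, w=5.0, n_cols=120))
    shifted = fit_cauchy_profile(make_profile(A=800, B=150, i_mid=55, w=5.0, n_cols=120))
    assert shifted.i_mid - base.i_mid == pytest.approx(15.0, abs=0.05)
    assert shifted.A == pytest.approx(base.A, rel=1e-3)
    assert shifted.B == pytest.approx(base.B, rel=1e-3)
    assert shifted.w == pytest.approx(base.w, rel=1e-3)


def test_em_loglik_nondecreasing_on_noiseless_input():
    c = make_profile(A=2000, B=500, i_mid=48, w=6.0)
    lls = []
    for it in range(1, 25):
        f = fit_cauchy_profile(c, tol=0.0, max_iter=it)
        lls.append(profile_loglik(c, f))
    diffs = np.diff(lls)
    assert np.all(diffs >= -1e-9)


def test_em_flags_nonconvergence_without_raising():
    c = make_profile(A=1000, B=200, i_mid=51, w=5.5, noise_sd=50, seed=0)
    f = fit_cauchy_profile(c, tol=1e-15, max_iter=3)
    assert not f.converged
    assert f.iterations == 3


# ---------------------------------------------------------------------------
# auto-fluorescence

def test_autofluor_exact_proportionality():
    S = 2.0 * np.exp(0.01 * np.arange(20))
    a, s = autofluor_cell(400.0 * S, S)
    assert a == pytest.approx(400.0)
    assert s == pytest.approx(0.0, abs=1e-9)


def test_autofluor_unbiased_under_noise():
    rng = np.random.default_rng(11)
    S = 2.0 * np.exp(0.01 * np.arange(25))
    est = [autofluor_cell(420.0 * S + rng.normal(0, 50, S.size), S)[0]
           for _ in range(1000)]
    assert np.mean(est) == pytest.approx(420.0, rel=0.01)


def test_autofluor_posterior_matches_grid_maximization():
    """The closed-form a* and sigma_a match a brute-force scan of the
    marginalized posterior (scale prior on the noise, exponent -T/2)."""
    rng = np.random.default_rng(4)
    S = np.linspace(1.5, 4.0, 12)
    A = 300.0 * S + rng.normal(0, 40, S.size)
    a_star, sigma_a = autofluor_cell(A, S)
    T = S.size
    grid = np.linspace(a_star - 50, a_star + 50, 20001)
    quad = (np.mean(S * S) * (grid - np.mean(A * S) / np.mean(S * S)) ** 2
            + np.mean(A * A) - np.mean(A * S) ** 2 / np.mean(S * S))
    logp = -T / 2.0 * np.log(quad)
    assert grid[np.argmax(logp)] == pytest.approx(a_star, abs=0.01)
    # curvature of the log-posterior at the mode reproduces sigma_a
    d2 = np.gradient(np.gradient(logp, grid), grid)[np.argmax(logp)]
    assert np.sqrt(-1.0 / d2) == pytest.approx(sigma_a, rel=0.02)


def test_population_weighted_reduces_to_mean_for_equal_sigmas():
    a = np.array([400.0, 420.0, 440.0])
    s = np.array([5.0, 5.0, 5.0])
    res = autofluor_population(a, s, method="weighted")
    assert res.alpha == pytest.approx(a.mean())


def test_population_identical_cells_any_method():
    a = np.full(10, 433.0)
    s = np.full(10, 3.0)
    assert autofluor_population(a, s, "weighted").alpha == pytest.approx(433.0)
    assert autofluor_population(a, s, "mixture").alpha == pytest.approx(433.0)


def test_population_mixture_recovers_alpha_with_outliers():
    """284 cells, 30% uniform outliers: the mixture recovers the common
    auto-fluorescence within 2% and the inlier fraction within 0.1."""
    rng = np.random.default_rng(8)
    n = 284
    outlier = rng.uniform(size=n) < 0.30
    a = np.where(outlier, rng.uniform(300, 900, n), rng.normal(420.0, 8.0, n))
    s = rng.uniform(5.0, 12.0, n)
    a = a + rng.normal(0, s)
    res = autofluor_population(a, s, method="mixture")
    assert res.alpha == pytest.approx(420.0, rel=0.02)
    assert res.rho_inlier == pytest.approx(0.70, abs=0.1)


def test_correct_fluor_arithmetic():
    assert correct_fluor(1000.0, 2.0, 421.8) == pytest.approx(156.4)
    assert correct_fluor(77.0, 3.0, 0.0) == pytest.approx(77.0)
    out = correct_fluor(np.array([10.0]), np.array([1.0]), 50.0)
    assert out[0] == pytest.approx(-40.0)  # negative allowed


# ---------------------------------------------------------------------------
# decay

def test_decay_exact_exponential_recovered():
    t = np.arange(40) * 180.0
    g = 5000.0 * np.exp(-5.3e-5 * t)
    res = fit_decay([(0, t, g), (1, t, 2.0 * g)])
    assert res.mu_star == pytest.approx(5.3e-5, rel=1e-6)
    assert res.n_excluded == 0


def test_decay_window_filter_and_exclusion():
    t = np.arange(40) * 180.0
    g = 5000.0 * np.exp(-5.3e-5 * t)
    windows = [(0.0, 10 * 180.0)]
    res = fit_decay([(0, t, g), (1, t[:5], g[:5])], windows=windows, min_points=10)
    assert res.n_excluded == 1
    assert res.cell_ids.tolist() == [0]
    assert res.n_observations == 10


def test_decay_unbiased_with_shot_noise():
    rng = np.random.default_rng(17)
    t = np.arange(70) * 180.0
    series = []
    for i in range(120):
        g = rng.uniform(3000, 20000) * np.exp(-5.3e-5 * t)
        series.append((i, t, g + rng.normal(0, np.sqrt(g))))
    res = fit_decay(series)
    assert res.mu_star == pytest.approx(5.3e-5, rel=0.03)


def test_glucose_windows_from_schedule():
    sched = [(0.0, "glucose"), (14400.0, "lactose"), (28800.0, "glucose")]
    w = glucose_windows(sched, total_time=43200.0, settle_s=1800.0)
    assert w == [(1800.0, 14400.0), (30600.0, 43200.0)]


# ---------------------------------------------------------------------------
# error profile

def test_gfp_error_profile_shot_noise_exponent():
    """Pure shot noise: squared relative error ~ 1/G, exponent ~ -1."""
    rng = np.random.default_rng(23)
    pairs = []
    for _ in range(300):
        G = rng.uniform(200, 20000)
        obs = G + rng.normal(0, np.sqrt(G), 40)
        resid = np.log(obs) - np.log(G)
        pairs.append((np.full(40, G), resid))
    prof = gfp_error_profile(pairs)
    assert prof["powerlaw_exponent"] == pytest.approx(-1.0, abs=0.15)


def test_gfp_error_profile_noiseless_is_zero():
    prof = gfp_error_profile([(np.full(20, 1000.0), np.zeros(20))], n_bins=2)
    assert np.allclose(prof["sq_rel_error_mean"], 0.0)


@settings(derandomize=True, max_examples=25)
@given(st.floats(100.0, 5000.0), st.floats(10.0, 2000.0),
       st.floats(40.0, 60.0), st.floats(3.0, 9.0))
def test_em_fixed_point_at_truth(A, B, i_mid, w):
    """On noiseless profiles the EM iteration keeps the true parameters."""
    c = make_profile(A=A, B=B, i_mid=i_mid, w=w)
    f = fit_cauchy_profile(c)
    assert f.A == pytest.approx(A, rel=2e-2)
    assert f.B == pytest.approx(B, rel=2e-2)
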