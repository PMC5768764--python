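"""Per-cell fluorescence estimation.

The total fluorescence of a cell is estimated from the column sums of its
image segment, which follow a Cauchy (Lorentzian) peak on a flat background:

    c_i = noise + B + A / (1 + ((i - i_mid)/w)^2)

fitted by an expectation-maximization loop under Gaussian measurement noise.
The amplitude A is proportional to the cell's total fluorophore content plus
an auto-fluorescence contribution proportional to cell size, which is
estimated on reporter-free cells and subtracted (A~ = A - alpha * S). The
slow exponential loss of signal during production-free phases gives the
combined bleaching + degradation rate mu and, through the residuals of those
fits, the measurement-error profile of the fluorescence estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import linregress

logger = logging.getLogger(__name__)


@dataclass
class ProfileFit:
    """Cauchy + background decomposition of a fluorescence column-sum profile."""

    A: float
    B: float
    i_mid: float
    w: float
    iterations: int
    converged: bool

    def curve(self, n_cols: int) -> np.ndarray:
        i = np.arange(n_cols, dtype=float)
        return self.B + self.A / (1.0 + ((i - self.i_mid) / self.w) ** 2)


def column_sums(segment_image: np.ndarray) -> np.ndarray:
    """Column sums c_i of a 2D cell-segment image (sum over rows)."""
    seg = np.asarray(segment_image, dtype=float)
    if seg.ndim != 2:
        raise ValueError(f"expected a 2D image segment, got ndim={seg.ndim}")
    return seg.sum(axis=0)


def _rho(i: np.ndarray, i_mid: float, w: float) -> np.ndarray:
    return 1.0 / (1.0 + ((i - i_mid) / w) ** 2)


def _root_near(func, x0: float, lo: float, hi: float, step: float) -> float:
    """Bracketed root search around x0; keeps x0 if no sign change is found."""
    a, b = x0 - step, x0 + step
    fa, fb = func(a), func(b)
    for _ in range(40):
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb <= 0:
            if fa == 0:
                return a
            if fb == 0:
                return b
            return brentq(func, a, b, xtol=1e-10)
        a = max(lo, a - step)
        b = min(hi, b + step)
        fa, fb = func(a), func(b)
        if a == lo and b == hi:
            break
    if np.isfinite(fa) and np.isfinite(fb) and fa * fb <= 0:
        return brentq(func, a, b, xtol=1e-10)
    logger.debug("no sign change for root search around %.3f; keeping value", x0)
    return x0


def fit_cauchy_profile(profile: np.ndarray, tol: float = 1e-6,
                       max_iter: int = 500) -> ProfileFit:
    """EM fit of the Cauchy + background model to a column-sum profile.

    Initialization: B = c_min, A = c_max - c_min, w = 5.5, i_mid = centre of
    the profile. Each iteration multiplicatively reassigns counts between
    background and signal, then updates the peak centre and width by finding
    the zero of the corresponding stationarity condition near the current
    value. Iterates until the largest relative parameter change falls below
    ``tol`` or ``max_iter`` is reached; non-convergence is flagged on the
    result, never raised.
    """
    c = np.asarray(profile, dtype=float)
    N = c.size
    if N < 5:
        raise ValueError(f"profile must have >= 5 columns, got {N}")
    i = np.arange(N, dtype=float)

    B = float(c.min())
    A = float(c.max() - c.min())
    w = 5.5
    i_mid = N / 2.0
    if B <= 0:          # multiplicative updates need a positive starting point
        B = max(1e-12, float(np.abs(c).mean()) * 1e-6)
    if A <= 0:
        A = max(1e-12, B * 1e-6)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rho_i = _rho(i, i_mid, w)
        rho_sum = rho_i.sum()
        denom = B + A * rho_i
        B_new = float(np.mean(B * c / denom))
        A_new = float(np.sum(A * c * rho_i / denom) / rho_sum)

        def d_imid(m, A_=A_new, B_=B_new, w_=w):
            r = _rho(i, m, w_)
            return float(np.sum((i - m) * r * r * (-1.0 + c / (B_ + A_ * r))))

        i_mid_new = _root_near(d_imid, i_mid, 0.0, float(N), step=1.0)

        def d_w(wv, A_=A_new, B_=B_new, m_=i_mid_new):
            r = _rho(i, m_, wv)
            return float(np.sum(r * (1.0 - r) * (-1.0 + c / (B_ + A_ * r))))

        w_new = _root_near(d_w, w, 1e-3, float(N), step=0.5)

        old = np.array([A, B, i_mid, w])
        new = np.array([A_new, B_new, i_mid_new, w_new])
        rel = np.abs(new - old) / np.maximum(np.abs(old), 1e-12)
        A, B, i_mid, w = A_new, B_new, i_mid_new, w_new
        if rel.max() < tol:
            converged = True
            break

    return ProfileFit(A=A, B=B, i_mid=i_mid, w=float(abs(w)),
                      iterations=it, converged=converged)


def profile_loglik(profile: np.ndarray, fit: ProfileFit) -> float:
    """Gaussian log-likelihood (up to constants) of a profile under a fit.

    Used as a monotonicity surrogate for the EM loop: -N/2 * log(RSS).
    """
    c = np.asarray(profile, dtype=float)
    resid = c - fit.curve(c.size)
    rss = float(np.sum(resid ** 2))
    return -0.5 * c.size * np.log(max(rss, 1e-300))


# ---------------------------------------------------------------------------
# auto-fluorescence

@dataclass
class AutoFluorResult:
    """Population auto-fluorescence per micron of cell length."""

    alpha: float
    method: str                     # "weighted" or "mixture"
    rho_inlier: float | None = None  # mixture only: fraction of non-outlier cells
    width_W: float | None = None     # mixture only: support of the outlier uniform
    n_cells: int = 0


def autofluor_cell(amplitudes: np.ndarray, sizes_fit: np.ndarray) -> tuple[float, float]:
    """Per-cell auto-fluorescence slope a* and its posterior sd.

    Fits A_t = a * S~_t over the cell's time points, with S~_t the sizes from
    the cell's exponential growth fit (more accurate than the raw sizes).
    Marginalizing the unknown Gaussian noise scale gives
    a* = <A S~>/<S~^2> and sigma_a = sqrt((1/T)[<A^2>/<S~^2> - a*^2]).
    """
    A = np.asarray(amplitudes, dtype=float)
    S = np.asarray(sizes_fit, dtype=float)
    if A.shape != S.shape or A.ndim != 1:
        raise ValueError("amplitudes and sizes must be 1D arrays of equal length")
    T = A.size
    if T < 3:
        raise ValueError(f"need >= 3 time points, got {T}")
    mean_S2 = float(np.mean(S * S))
    if mean_S2 <= 0:
        raise ValueError("degenerate sizes: <S~^2> must be positive")
    a_star = float(np.mean(A * S) / mean_S2)
    var_term = float(np.mean(A * A) / mean_S2) - a_star ** 2
    sigma_a = float(np.sqrt(max(var_term, 0.0) / T))
    return a_star, sigma_a


def autofluor_population(a_stars: np.ndarray, sigma_as: np.ndarray,
                         method: str = "mixture",
                         sigma_floor_rel: float = 1e-6) -> AutoFluorResult:
    """Combine per-cell auto-fluorescence estimates into a population value.

    ``weighted``: precision-weighted mean alpha = sum(a*/s^2)/sum(1/s^2).
    ``mixture``: maximize the likelihood of a Gaussian-inlier / uniform-outlier
    mixture over (alpha, rho) with outlier support W = max(a*) - min(a*);
    grid scan then local polish.
    """
    a = np.asarray(a_stars, dtype=float)
    s = np.asarray(sigma_as, dtype=float).copy()
    if a.size < 2:
        raise ValueError(f"need >= 2 cells, got {a.size}")
    floor = sigma_floor_rel * max(float(np.median(np.abs(a))), 1e-300)
    n_floored = int(np.sum(s < floor))
    if n_floored:
        logger.info("autofluor_population: flooring %d sigma_a values at %.3g",
                    n_floored, floor)
        s = np.maximum(s, floor)

    weights = 1.0 / (s * s)
    alpha_w = float(np.sum(a * weights) / np.sum(weights))
    if method == "weighted":
        return AutoFluorResult(alpha=alpha_w, method="weighted", n_cells=a.size)
    if method != "mixture":
        raise ValueError(f"unknown method {method!r}")

    W = float(a.max() - a.min())
    if W <= 0:  # all estimates identical
        return AutoFluorResult(alpha=float(a[0]), method="mixture", rho_inlier=1.0,
                               width_W=0.0, n_cells=a.size)

    def negll(params):
        alpha, rho = params
        rho = np.clip(rho, 1e-9, 1.0)
        gauss = rho * np.exp(-0.5 * ((alpha - a) / s) ** 2) / (np.sqrt(2 * np.pi) * s)
        lik = (1.0 - rho) / W + gauss
        return -float(np.sum(np.log(np.maximum(lik, 1e-300))))

    alphas = np.linspace(a.min(), a.max(), 201)
    rhos = np.linspace(0.01, 1.0, 34)
    best = None
    for r in rhos:
        vals = [negll((al, r)) for al in alphas]
        k = int(np.argmin(vals))
        if best is None or vals[k] < best[0]:
            best = (vals[k], alphas[k], r)
    res = minimize(negll, x0=[best[1], best[2]], method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    alpha_m, rho_m = float(res.x[0]), float(np.clip(res.x[1], 0.0, 1.0))
    return AutoFluorResult(alpha=alpha_m, method="mixture", rho_inlier=rho_m,
                           width_W=W, n_cells=a.size)


def correct_fluor(A, S, alpha: float):
    """Auto-fluorescence corrected level A~ = A - alpha * S.

    Negative results are permitted (measurement noise around zero signal).
    """
    A = np.asarray(A, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("sizes must be >= 0")
    out = A - alpha * S
    if np.any(out < 0):
        logger.debug("correct_fluor: %d corrected values are negative",
                     int(np.sum(out < 0)))
    return out


# ---------------------------------------------------------------------------
# bleaching / degradation

@dataclass
class DecayResult:
    """Per-cell and combined bleaching + degradation rate (1/second)."""

    mu: np.ndarray            # per-cell rates
    mu_sd: np.ndarray         # per-cell regression sds
    cell_ids: np.ndarray
    mu_star: float            # precision-weighted combined rate
    mu_star_sd: float
    n_excluded: int           # cells with too few points in the window
    n_observations: int


def fit_decay(cell_series: list[tuple[int, np.ndarray, np.ndarray]],
              windows: list[tuple[float, float]] | None = None,
              min_points: int = 10) -> DecayResult:
    """Estimate the fluorescence decay rate mu from production-free phases.

    ``cell_series`` holds (cell_id, times_s, corrected_fluorescence) per cell.
    Only observations inside ``windows`` (e.g. from 30 min after a switch to
    the repressing condition until the next induction) are used, and only
    cells with at least ``min_points`` such observations. Per cell, -mu is
    the slope of a linear regression of log(level) on time; the combined
    mu* is the precision-weighted mean of the per-cell rates.
    """
    mus, sds, ids = [], [], []
    n_excluded = 0
    n_obs = 0
    for cell_id, t, g in cell_series:
        t = np.asarray(t, dtype=float)
        g = np.asarray(g, dtype=float)
        if windows is not None:
            mask = np.zeros(t.size, dtype=bool)
            for lo, hi in windows:
                mask |= (t >= lo) & (t < hi)
        else:
            mask = np.ones(t.size, dtype=bool)
        mask &= g > 0
        if int(mask.sum()) < min_points:
            n_excluded += 1
            continue
        tt, gg = t[mask], np.log(g[mask])
        fit = linregress(tt, gg)
        sd = float(fit.stderr) if np.isfinite(fit.stderr) else 0.0
        mus.append(-float(fit.slope))
        sds.append(sd)
        ids.append(cell_id)
        n_obs += int(mask.sum())
    if not mus:
        raise ValueError("no cells pass the decay-window criteria")
    mu = np.array(mus)
    sd = np.array(sds)
    floor = max(1e-12 * max(float(np.median(np.abs(mu))), 1e-300), 1e-30)
    wts = 1.0 / np.maximum(sd, floor) ** 2
    mu_star = float(np.sum(mu * wts) / np.sum(wts))
    mu_star_sd = float(np.sqrt(1.0 / np.sum(wts)))
    return DecayResult(mu=mu, mu_sd=sd, cell_ids=np.array(ids), mu_star=mu_star,
                       mu_star_sd=mu_star_sd, n_excluded=n_excluded,
                       n_observations=n_obs)


def glucose_windows(switch_schedule: list[tuple[float, str]], total_time: float,
                    settle_s: float = 1800.0) -> list[tuple[float, float]]:
    """Production-free analysis windows: from ``settle_s`` after each switch to
    the repressing condition until the next switch (or the end of the movie)."""
    windows = []
    for k, (t0, cond) in enumerate(switch_schedule):
        if cond != "glucose":
            continue
        t1 = switch_schedule[k + 1][0] if k + 1 < len(switch_schedule) else total_time
        if t0 + settle_s < t1:
            windows.append((t0 + settle_s, t1))
    return windows


# ---------------------------------------------------------------------------
# measurement-error profile

def gfp_error_profile(residual_pairs: list[tuple[np.ndarray, np.ndarray]],
                      n_bins: int = 10) -> dict:
    """Relative-error profile of GFP estimates from decay-fit residuals.

    ``residual_pairs`` holds (levels, residuals_of_log_fit) per cell; the
    squared relative error of each observation is the squared residual of the
    log fit (equivalently, squared residual normalized by the squared value).
    Observations are binned by level; per-bin means and standard errors of the
    squared relative error are reported along with the log-log regression
    exponent of squared relative error versus level (pure shot noise: -1).
    """
    levels = np.concatenate([np.asarray(lv, dtype=float) for lv, _ in residual_pairs])
    resid = np.concatenate([np.asarray(r, dtype=float) for _, r in residual_pairs])
    ok = levels > 0
    levels, resid = levels[ok], resid[ok]
    if levels.size == 0:
        raise ValueError("no positive levels to profile")
    sq_rel = resid ** 2
    edges = np.quantile(levels, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, levels, side="right") - 1, 0, len(edges) - 2)
    centers, means, ses, counts = [], [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            logger.warning("gfp_error_profile: dropping empty bin %d", b)
            continue
        centers.append(float(np.mean(levels[sel])))
        means.append(float(np.mean(sq_rel[sel])))
        ses.append(float(np.std(sq_rel[sel], ddof=1) / np.sqrt(n)) if n > 1 else 0.0)
        counts.append(n)
    centers = np.array(centers)
    means = np.array(means)
    pos = means > 0
    if int(pos.sum()) >= 2:
        slope = float(linregress(np.log(centers[pos]), np.log(means[pos])).slope)
    else:
        slope = float("nan")
    return {
        "bin_centers": centers,
        "sq_rel_error_mean": means,
        "sq_rel_error_se": np.array(ses),
        "counts": np.array(counts),
        "rel_error": np.sqrt(means),
        "powerlaw_exponent": slope,
    }
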