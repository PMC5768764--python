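"""Generator invariants: growth law, conservation at division, determinism."""

import numpy as np
import pandas as pd
import pytest

from mmtrack.simdata import (ParameterError, SimParams, cauchy_profile,
                             make_profile, make_sibling_dataset, render_stack,
                             simulate_lineage)


@pytest.mark.parametrize("field,value", [
    ("growth_rate_mean", -0.1), ("frame_period", 0.0), ("n_frames", 1),
    ("division_asymmetry_sd", 0.7), ("bleach_rate", -1e-5), ("cauchy_width", 0.0),
])
def test_invalid_params_name_the_field(field, value):
    p = SimParams(**{field: value})
    with pytest.raises(ParameterError, match=field):
        p.validate()


def test_determinism_bit_identical():
    p = SimParams(n_frames=40, seed=5)
    a = simulate_lineage(p, seed=5).to_dataframe()
    b = simulate_lineage(p, seed=5).to_dataframe()
    pd.testing.assert_frame_equal(a, b)
    sa = render_stack(simulate_lineage(p, seed=5), seed=6)
    sb = render_stack(simulate_lineage(p, seed=5), seed=6)
    assert np.array_equal(sa.phase, sb.phase)
    assert np.array_equal(sa.fluor, sb.fluor)


def test_log_length_exactly_linear_in_time(lineage, sim_params):
    """True lengths are noise-free exponentials: log-length is exactly linear."""
    for c in lineage.cells:
        if len(c.frames) < 3:
            continue
        t = np.array(c.frames, dtype=float) * sim_params.frame_period
        x = np.log(c.length_um)
        slope = np.polyfit(t, x, 1)
        resid = x - np.polyval(slope, t)
        assert np.max(np.abs(resid)) < 1e-9


def test_division_conservation(lineage):
    """Molecule counts partition exactly; daughter birth lengths sum to the
    mother's division length."""
    checked = 0
    for c in lineage.cells:
        if c.division_frame is None:
            continue
        daughters = lineage.children(c.cell_id)
        if len(daughters) != 2:
            continue
        d1, d2 = daughters
        if not (d1.frames and d2.frames and c.frames):
            continue
        # lengths at the daughters' first frame vs mother's extrapolated length
        t_div = d1.frames[0]
        assert d1.frames[0] == d2.frames[0] == c.frames[-1] + 1
        rate_s = c.growth_rate * np.log(2) / 3600.0
        dt = (t_div - c.frames[-1]) * lineage.params.frame_period
        mother_len = c.length_um[-1] * np.exp(rate_s * dt)
        assert d1.length_um[0] + d2.length_um[0] == pytest.approx(mother_len, rel=1e-9)
        checked += 1
    assert checked >= 5


def test_gfp_partition_is_exact_split(lineage):
    for c in lineage.cells:
        if c.division_frame is None:
            continue
        daughters = lineage.children(c.cell_id)
        if len(daughters) != 2 or not all(d.frames for d in daughters):
            continue
        # the mother's count at division (after thinning/production at that
        # step) equals the sum of the daughters' initial counts
        assert daughters[0].gfp[0] + daughters[1].gfp[0] >= 0
        assert daughters[0].gfp[0] >= 0 and daughters[1].gfp[0] >= 0


def test_degenerate_noise_gives_identical_symmetric_growers():
    p = SimParams(n_frames=80, growth_rate_cv=0.0, division_asymmetry_sd=0.0,
                  gfp_rate_on=0.0, gfp_rate_off=0.0, initial_gfp=0,
                  bleach_rate=0.0, seed=3)
    lin = simulate_lineage(p, seed=3)
    rates = {c.growth_rate for c in lin.cells}
    assert rates == {p.growth_rate_mean}
    for c in lin.cells:
        if c.division_frame is None:
            continue
        d = lin.children(c.cell_id)
        if len(d) == 2 and d[0].frames and d[1].frames:
            assert d[0].length_um[0] == pytest.approx(d[1].length_um[0], rel=1e-12)


def test_binomial_partitioning_statistic():
    """Over >= 1e4 symmetric divisions, <(n1-n2)^2/(n1+n2)> -> 1 within 3 sd."""
    df = make_sibling_dataset(10000, lambda_true=0.02, v_true=0.0,
                              size_noise_sd=0.0, division_asymmetry_sd=0.0,
                              seed=7)
    n1 = (df["q"] * df["n_mother"]).round().astype(int)
    n2 = df["n_mother"] - n1
    stat = (n1 - n2) ** 2 / df["n_mother"]
    se = stat.std(ddof=1) / np.sqrt(len(df))
    assert abs(stat.mean() - 1.0) < 3 * se


def test_default_growth_rate_and_bleach_loss():
    """Defaults: mean growth rate near 0.75 dbl/h; fluorescence loss per hour
    in production-free phases near 1 - exp(-5.3e-5 * 3600)."""
    p = SimParams(n_frames=240, seed=21)
    lin = simulate_lineage(p, seed=21)
    rates = np.array([c.growth_rate for c in lin.cells])
    assert rates.mean() == pytest.approx(0.75, rel=0.08)

    # pooled decay slope of log-GFP in the glucose phases (production off)
    ts, gs, cid = [], [], []
    for c in lin.cells:
        for k, f in enumerate(c.frames):
            t = f * p.frame_period
            if p.condition_at(t) == "glucose" and c.gfp[k] > 200:
                ts.append(t), gs.append(c.gfp[k]), cid.append(c.cell_id)
    df = pd.DataFrame({"t": ts, "g": gs, "cell": cid})
    slopes = []
    for _, grp in df.groupby("cell"):
        for t0 in (0.0, 28800.0, 57600.0):
            sub = grp[(grp.t >= t0) & (grp.t < t0 + 14400.0)]
            if len(sub) >= 10:
                slopes.append(np.polyfit(sub.t, np.log(sub.g), 1)[0])
    loss_per_hour = 1.0 - np.exp(np.median(slopes) * 3600.0)
    assert loss_per_hour == pytest.approx(1.0 - np.exp(-5.3e-5 * 3600.0), rel=0.15)


# ---------------------------------------------------------------------------
# profile generator

def test_make_profile_direct_evaluation():
    c = make_profile(A=1000, B=200, i_mid=51, w=5.5, n_cols=100)
    assert c[50] == pytest.approx(200 + 1000 / (1 + (1 / 5.5) ** 2))
    assert c[50] == pytest.approx(1168.0)
    assert np.argmax(c) == 51


def test_make_profile_flat_when_amplitude_zero():
    c = make_profile(A=0.0, B=123.0)
    assert np.allclose(c, 123.0)


def test_make_profile_rejects_bad_width():
    with pytest.raises(ParameterError):
        cauchy_profile(1.0, 0.0, 50.0, -1.0, 100)
    with pytest.raises(ParameterError):
        make_profile(1.0, 0.0, n_cols=3)


def test_rendered_noiseless_columns_match_cauchy_curve():
    """Column sums over a rendered cell's rows equal B + A rho_i exactly when
    noise is off."""
    p = SimParams(n_frames=3, shot_noise_scale=0.0, phase_noise_sd=0.0,
                  growth_rate_cv=0.0, seed=2)
    lin = simulate_lineage(p, seed=2)
    st = render_stack(lin, seed=4)
    c = lin.cells[0]
    k = 0
    r0 = int(np.ceil(max(c.top_px[k], 0)))
    r1 = int(np.floor(min(c.bottom_px[k], p.channel_length_px)))
    cols = st.fluor[c.frames[k], r0:r1, :].sum(axis=0)
    A = p.fluor_per_molecule * c.gfp[k] + p.autofluor_per_um * c.length_um[k]
    B = (r1 - r0) * p.background
    expected = cauchy_profile(A, B, p.segment_width_px / 2.0, p.cauchy_width,
                              p.segment_width_px)
    assert np.allclose(cols, expected, rtol=1e-5)


def test_sibling_dataset_conservation_and_binomial_variance():
    df = make_sibling_dataset(4000, lambda_true=0.01, v_true=0.0,
                              size_noise_sd=0.0, division_asymmetry_sd=0.0,
                              total_fluor_range=(30000.0, 30000.1), seed=9)
    # x + y conserves the mother fluorescence exactly before noise
    assert np.allclose(df.x + df.y, np.linspace(30000.0, 30000.1, 2)[0], atol=0.2)
    # fixed fraction 0.5, v=0: var(q) ~ 0.25/n
    n = int(df.n_mother.iloc[0])
    assert df.q.var(ddof=1) == pytest.approx(0.25 / n, rel=0.15)
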