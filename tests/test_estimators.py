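"""MR estimators against independent oracles and their invariances."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from summr import (MethodError, build_set, cochran_q, egger, f_statistic,
                   gen_two_sample, ivw, leave_one_out, max_likelihood, mvmr,
                   wald_ratios, weighted_median)
from summr.estimators import significance_label, weighted_median_estimate

from conftest import build_hset


def random_hset(rng, J=12):
    gamma = rng.uniform(0.05, 0.3, J) * rng.choice([-1, 1], J)
    sigma_x = rng.uniform(0.005, 0.02, J)
    Gamma = 0.4 * gamma + rng.normal(0, 0.05, J)
    sigma_y = rng.uniform(0.01, 0.08, J)
    return build_hset(gamma, sigma_x, Gamma, sigma_y)


# ---------------------------------------------------------------- Wald ratios

def test_wald_ratio_arithmetic(make_hset):
    hs = make_hset([0.1, 0.1], 0.01, [0.0, 0.05], 0.02)
    ratios = wald_ratios(hs)
    assert ratios[0].theta == 0.0
    assert ratios[1].theta == pytest.approx(0.5)
    assert ratios[1].se == pytest.approx(0.2)


def test_wald_ratio_rejects_zero_gamma(make_hset):
    hs = make_hset([0.0, 0.1], 0.01, [0.01, 0.05], 0.02)
    ratios = wald_ratios(hs)
    assert [r.rsid for r in ratios] == ["rs2"]


def test_wald_ratio_second_order_se(make_hset):
    hs = make_hset([0.1], 0.01, [0.05], 0.02)
    first = wald_ratios(hs)[0].se
    second = wald_ratios(hs, second_order=True)[0].se
    expected = np.sqrt(0.02**2 / 0.1**2 + 0.05**2 * 0.01**2 / 0.1**4)
    assert second == pytest.approx(expected)
    assert second > first


def test_first_order_ratio_se_matches_simulation():
    """Delta-method SE vs Monte-Carlo SE of simulated ratios at strong
    instrument (error < 5%)."""
    rng = np.random.default_rng(7)
    gamma, sigma_x, theta, sigma_y = 0.1, 0.003, 0.5, 0.02
    n = 100_000
    g = gamma + sigma_x * rng.standard_normal(n)
    G = theta * gamma + sigma_y * rng.standard_normal(n)
    mc_se = np.std(G / g, ddof=1)
    assert sigma_y / gamma == pytest.approx(mc_se, rel=0.05)


# ------------------------------------------------------------------------ IVW

def test_ivw_exact_collinear_two_snps(make_hset):
    hs = make_hset([0.1, 0.2], 0.01, [0.05, 0.10], 0.02)
    res = ivw(hs)
    assert res.theta == pytest.approx(0.5)
    assert res.q_statistic == pytest.approx(0.0, abs=1e-24)
    # scale floor: random-effect SE equals fixed SE here
    assert res.se == pytest.approx(ivw(hs, random_effects=False).se)


def test_ivw_symmetric_ratios_give_zero(make_hset):
    hs = make_hset([0.1, 0.1], 0.01, [0.05, -0.05], 0.02)
    assert ivw(hs).theta == pytest.approx(0.0)


def test_ivw_matches_wls_oracle(rng):
    hs = random_hset(rng, J=10)
    g, _, G, sy = hs.arrays()
    fit = sm.WLS(G, g[:, None], weights=1.0 / sy**2).fit()
    res = ivw(hs)
    assert res.theta == pytest.approx(fit.params[0], abs=1e-10)
    # fixed SE is the WLS normal-equation SE with unit dispersion
    fixed = ivw(hs, random_effects=False)
    assert fixed.se == pytest.approx(
        float(np.sqrt(1.0 / np.sum(g**2 / sy**2))), abs=1e-12)


def test_ivw_single_snp_is_an_error(make_hset):
    with pytest.raises(MethodError):
        ivw(make_hset([0.1], 0.01, [0.05], 0.02))


def test_fixed_se_never_exceeds_random_effect_se(rng):
    for _ in range(10):
        hs = random_hset(rng)
        assert ivw(hs, random_effects=False).se <= ivw(hs).se + 1e-15


# ------------------------------------------------------------------ Cochran Q

def test_cochran_q_collinear_is_zero(make_hset):
    hs = make_hset([0.1, 0.2], 0.01, [0.05, 0.10], 0.02)
    q, df, p = cochran_q(hs, 0.5)
    assert q == pytest.approx(0.0, abs=1e-24)
    assert df == 1 and p == pytest.approx(1.0)


def test_cochran_q_outlier_dominates(make_hset):
    hs = make_hset([0.1, 0.1, 0.1], 0.01, [0.05, 0.05, 0.50], 0.02)
    q, _, _ = cochran_q(hs, 0.5)
    outlier_term = ((0.50 - 0.5 * 0.1) / 0.02) ** 2
    assert outlier_term / q > 0.99


def test_cochran_q_null_calibration():
    """Q/df averages 1 under a correctly specified null."""
    rng = np.random.default_rng(99)
    ratios = []
    for _ in range(1000):
        g = rng.uniform(0.05, 0.2, 10)
        sy = rng.uniform(0.01, 0.05, 10)
        G = 0.3 * g + sy * rng.standard_normal(10)
        hs = build_hset(g, 0.001, G, sy)
        q, df, _ = cochran_q(hs, ivw(hs).theta)
        ratios.append(q / df)
    # Q/(J-1) with estimated theta is slightly below 1; loose band
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


# ----------------------------------------------------------- max likelihood

def test_ml_noiseless_proportional_data(make_hset):
    g = np.array([0.05, 0.1, 0.2, 0.3])
    hs = build_hset(g, 0.01, 0.37 * g, 0.02)
    assert max_likelihood(hs).theta == pytest.approx(0.37, abs=1e-8)


def test_ml_single_snp_collapses_to_wald(make_hset):
    hs = make_hset([0.1], 0.01, [0.05], 0.02)
    assert max_likelihood(hs).theta == pytest.approx(0.5, abs=1e-8)


def test_ml_matches_grid_search_oracle(rng):
    """Dense grid over theta, optimizing each SNP's nuisance true effect
    analytically inside the full likelihood -- an independent algebra path."""
    hs = random_hset(rng, J=5)
    g, sx, G, sy = hs.arrays()

    grid = np.linspace(-2, 2, 400_001)[:, None]
    # optimal nuisance g_j* per (theta, SNP), then the full likelihood
    gstar = (g / sx**2 + grid * G / sy**2) / (1 / sx**2 + grid**2 / sy**2)
    loglik = np.sum(-0.5 * (g - gstar) ** 2 / sx**2
                    - 0.5 * (G - grid * gstar) ** 2 / sy**2, axis=1)
    oracle = float(grid[np.argmax(loglik), 0])
    assert max_likelihood(hs).theta == pytest.approx(oracle, abs=1e-4)


# ------------------------------------------------------------ weighted median

def test_weighted_median_middle_of_three(make_hset):
    # equal SEs, ratios 1,2,3: the 50% point hits the middle ratio
    hs = make_hset([0.1, 0.1, 0.1], 0.01, [0.1, 0.2, 0.3], 0.02)
    res = weighted_median(hs, n_boot=200, seed=1)
    assert res.theta == pytest.approx(2.0)


def test_weighted_median_constant_ratios(make_hset):
    hs = make_hset([0.1, 0.2, 0.4], 0.0001, [0.07, 0.14, 0.28], 0.0001)
    res = weighted_median(hs, n_boot=200, seed=1)
    assert res.theta == pytest.approx(0.7, abs=1e-9)
    assert res.se < 0.01


def test_weighted_median_within_ratio_range(rng):
    for _ in range(20):
        hs = random_hset(rng)
        ratios = [r.theta for r in wald_ratios(hs)]
        est = weighted_median_estimate(hs)
        assert min(ratios) <= est <= max(ratios)


def test_weighted_median_deterministic_given_seed(rng):
    hs = random_hset(rng)
    a = weighted_median(hs, n_boot=300, seed=42)
    b = weighted_median(hs, n_boot=300, seed=42)
    assert a == b


def test_weighted_median_needs_three_snps(make_hset):
    with pytest.raises(MethodError):
        weighted_median(make_hset([0.1, 0.2], 0.01, [0.05, 0.1], 0.02))


# ---------------------------------------------------------------------- Egger

def test_egger_recovers_exact_line(make_hset):
    g = np.array([0.05, 0.1, 0.2, 0.4])
    hs = build_hset(g, 0.01, 0.01 + 0.3 * g, 0.02)
    res = egger(hs)
    assert res.intercept == pytest.approx(0.01, abs=1e-12)
    assert res.theta == pytest.approx(0.3, abs=1e-12)


def test_egger_constant_pleiotropy_null_slope():
    """theta=0 with constant direct effects: intercept absorbs them."""
    rng = np.random.default_rng(5)
    g = rng.uniform(0.05, 0.3, 50)
    sy = np.full(50, 0.002)
    G = 0.04 + sy * rng.standard_normal(50)
    hs = build_hset(g, 0.001, G, sy)
    res = egger(hs)
    assert res.intercept == pytest.approx(0.04, abs=0.005)
    assert abs(res.theta) < 0.05


def test_egger_matches_wls_oracle_with_intercept(rng):
    hs = random_hset(rng, J=10)
    g, _, G, sy = hs.arrays()
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    fit = sm.WLS(G, sm.add_constant(g), weights=1.0 / sy**2).fit()
    res = egger(hs)
    assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
    assert res.theta == pytest.approx(fit.params[1], abs=1e-10)


def test_egger_orientation_invariance(rng):
    """Flipping (gamma, Gamma) signs jointly for any subset cannot change
    the Egger fit (all SNPs are re-oriented internally)."""
    hs = random_hset(rng, J=8)
    table = hs.table.copy()
    flip = np.array([1, -1, 1, -1, -1, 1, 1, -1.0])
    table["gamma"] *= flip
    table["Gamma"] *= flip
    from summr.harmonize import HarmonizedInstrumentSet
    res_a, res_b = egger(hs), egger(HarmonizedInstrumentSet(table))
    assert res_a.theta == pytest.approx(res_b.theta, abs=1e-12)
    assert res_a.intercept == pytest.approx(res_b.intercept, abs=1e-12)


# --------------------------------------------------------------- F statistic

def test_f_statistic_arithmetic(make_hset):
    hs = make_hset([0.03, 0.0], 0.003, [0.0, 0.0], 0.02)
    per_snp, overall = f_statistic(hs)
    assert per_snp[0] == pytest.approx(100.0)
    assert per_snp[1] == 0.0
    assert overall == pytest.approx(50.0)


def test_f_statistic_of_default_synthetic_instruments():
    """Instruments explaining ~1% of exposure variance in a 941k-sample
    study give an overall F on the order of 10^2."""
    exp, out, ivs, _ = gen_two_sample(J=99, seed=21)
    hs = build_set(exp, out, ivs)
    _, overall = f_statistic(hs)
    assert 50 < overall < 200


# -------------------------------------------------------------- leave-one-out

def test_leave_one_out_homogeneous_no_flags(make_hset):
    g = np.linspace(0.05, 0.3, 8)
    hs = build_hset(g, 0.01, 0.4 * g, 0.02)
    table = leave_one_out(hs)
    assert len(table) == 8
    assert not table["outside_full_ci"].any()


def test_leave_one_out_detects_planted_outlier():
    rng = np.random.default_rng(31)
    g = rng.uniform(0.1, 0.3, 12)
    sy = np.full(12, 0.004)
    G = 0.4 * g + sy * rng.standard_normal(12)
    G[5] += 0.4  # gross outlier
    hs = build_hset(g, 0.001, G, sy)
    table = leave_one_out(hs)
    shifts = (table["theta"] - ivw(hs).theta).abs()
    assert table.loc[shifts.idxmax(), "omitted_rsid"] == "rs6"


def test_leave_one_out_three_snps(make_hset):
    hs = make_hset([0.1, 0.2, 0.3], 0.01, [0.05, 0.1, 0.15], 0.02)
    table = leave_one_out(hs)
    assert len(table) == 3
    assert (table["n_snp"] == 2).all()


# ----------------------------------------------------------------------- MVMR

def test_mvmr_reduces_to_ivw_with_null_covariate(rng):
    import pandas as pd
    hs = random_hset(rng, J=12)
    cov = pd.DataFrame({"bmi": dict.fromkeys(hs.rsids(), 0.0)})
    res = mvmr(hs, cov)
    assert res.theta[0] == pytest.approx(ivw(hs).theta, abs=1e-12)
    assert res.theta[1] == 0.0 and res.pvalue[1] == 1.0


def test_mvmr_matches_two_column_wls_oracle(rng):
    import pandas as pd
    hs = random_hset(rng, J=12)
    cov_beta = rng.normal(0, 0.1, 12)
    cov = pd.DataFrame({"bmi": dict(zip(hs.rsids(), cov_beta))})
    g, _, G, sy = hs.arrays()
    X = np.column_stack([g, cov.loc[hs.rsids(), "bmi"]])
    fit = sm.WLS(G, X, weights=1.0 / sy**2).fit()
    res = mvmr(hs, cov)
    assert res.theta == pytest.approx(tuple(fit.params), abs=1e-10)


def test_mvmr_drops_snps_missing_covariate(rng):
    import pandas as pd
    hs = random_hset(rng, J=12)
    rsids = hs.rsids()[:9]
    cov = pd.DataFrame({"bmi": dict(zip(rsids, rng.normal(0, 0.1, 9)))})
    res = mvmr(hs, cov)
    assert res.n_snp == 9 and res.n_dropped == 3


def test_mvmr_rank_deficiency_names_exposures(rng):
    import pandas as pd
    hs = random_hset(rng, J=12)
    g = hs.table["gamma"]
    cov = pd.DataFrame({"copy": dict(zip(hs.rsids(), 2.0 * g))})
    with pytest.raises(MethodError, match="collinear"):
        mvmr(hs, cov)


# ------------------------------------------------------------- invariances

@settings(derandomize=True, max_examples=30, deadline=None)
@given(c=st.floats(0.1, 5.0), flip=st.booleans())
def test_scale_and_sign_equivariance(c, flip):
    """Multiplying all Gamma and sigma_y by c scales every estimate by c;
    jointly flipping gamma and Gamma signs changes nothing."""
    rng = np.random.default_rng(77)
    hs = random_hset(rng, J=9)
    table = hs.table.copy()
    table["Gamma"] *= c
    table["sigma_y"] *= c
    if flip:
        table["gamma"] *= -1
        table["Gamma"] *= -1
    from summr.harmonize import HarmonizedInstrumentSet
    scaled = HarmonizedInstrumentSet(table)
    assert ivw(scaled).theta == pytest.approx(c * ivw(hs).theta, rel=1e-9)
    assert egger(scaled).theta == pytest.approx(c * egger(hs).theta, rel=1e-9)
    assert max_likelihood(scaled).theta == pytest.approx(
        c * max_likelihood(hs).theta, rel=1e-5, abs=1e-7)
    assert weighted_median_estimate(scaled) == pytest.approx(
        c * weighted_median_estimate(hs), rel=1e-9)


def test_significance_annotation_thresholds():
    assert significance_label(0.005) == "**"
    assert significance_label(0.02) == "*"
    assert significance_label(0.2) == ""
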