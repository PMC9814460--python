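"""Univariable MR estimators: Wald, IVW, MR-Egger, weighted median."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from directmr.simulate import SimConfig, simulate_summary
from directmr.harmonize import harmonize
from directmr.uvmr import (egger, ivw, subgroup_heterogeneity, wald_ratio,
                           weighted_median)

from conftest import make_hset, random_hset


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("g,G,seG,theta,se", [
    (0.10, 0.05, 0.01, 0.5, 0.1),
    (0.10, 0.0, 0.01, 0.0, 0.1),
    (-0.2, 0.05, 0.02, -0.25, 0.1),
])
def test_wald_ratio_hand_values(g, G, seG, theta, se):
    est = wald_ratio(make_hset([g], [0.01], [G], [seG]).records[0])
    assert est.theta == pytest.approx(theta)
    assert est.se == pytest.approx(se)


def test_wald_ratio_rejects_null_instrument():
    with pytest.raises(ValueError, match="zero exposure beta"):
        wald_ratio(make_hset([0.0], [0.01], [0.1], [0.01]).records[0])


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def test_single_snp_ivw_equals_wald():
    h = make_hset([0.1], [0.01], [0.05], [0.01])
    assert ivw(h).theta == pytest.approx(wald_ratio(h.records[0]).theta)
    assert ivw(h).se == pytest.approx(wald_ratio(h.records[0]).se)


def test_perfect_homogeneity_gives_ratio_and_zero_q(rng):
    g = rng.uniform(0.02, 0.2, 8)
    h = make_hset(g, np.full(8, 0.01), 0.3 * g, rng.uniform(0.005, 0.02, 8))
    est = ivw(h)
    assert est.theta == pytest.approx(0.3, abs=1e-12)
    assert est.q_stat == pytest.approx(0.0, abs=1e-18)
    assert est.method == "ivw_fixed"


def test_ivw_matches_weighted_regression_through_origin(rng):
    """Normal-equations oracle (statsmodels WLS, no intercept) to 1e-10."""
    for L in (5, 12, 30):
        h = random_hset(rng, L)
        a = h.arrays()
        fit = sm.WLS(a["Gamma"], a["gamma1"], weights=1.0 / a["se_G"]**2).fit()
        assert ivw(h).theta == pytest.approx(float(fit.params[0]), abs=1e-10)


def test_ivw_orientation_invariance(rng):
    h = random_hset(rng, 9)
    ref = ivw(h).theta
    a = h.arrays()
    g, G = a["gamma1"].copy(), a["Gamma"].copy()
    g[3] *= -1
    G[3] *= -1  # flip allele orientation of one record
    assert ivw(make_hset(g, a["se_g1"], G, a["se_G"])).theta == pytest.approx(ref, abs=1e-14)


def test_random_se_never_below_fixed(rng):
    for _ in range(20):
        h = random_hset(rng, int(rng.integers(2, 25)))
        fixed, random_ = ivw(h, "fixed"), ivw(h, "random")
        assert random_.se >= fixed.se - 1e-15
        assert random_.theta == fixed.theta
        if fixed.q_stat <= fixed.q_df:
            assert random_.se == pytest.approx(fixed.se)


def test_auto_mode_switches_on_heterogeneity(rng):
    g = rng.uniform(0.05, 0.2, 10)
    seG = np.full(10, 0.005)
    # grossly heterogeneous ratios -> Q p < 0.05 -> multiplicative inflation
    G = g * rng.uniform(-1, 1, 10)
    est = ivw(make_hset(g, np.full(10, 0.01), G, seG), "auto")
    assert est.method == "ivw_random"
    assert est.q_pvalue < 0.05
    assert est.se > ivw(make_hset(g, np.full(10, 0.01), G, seG), "fixed").se


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def test_egger_recovers_exact_line():
    h = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.03, 0.05, 0.07], [0.01] * 3)
    est = egger(h)
    assert est.theta == pytest.approx(0.2, abs=1e-12)
    assert est.egger_intercept == pytest.approx(0.01, abs=1e-12)
    assert est.q_stat == pytest.approx(0.0, abs=1e-16)


def test_egger_requires_three_snps_and_spread():
    with pytest.raises(ValueError, match="3 SNPs"):
        egger(make_hset([0.1, 0.2], [0.01] * 2, [0.0, 0.0], [0.01] * 2))
    with pytest.raises(ValueError, match="degenerate"):
        egger(make_hset([0.1] * 4, [0.01] * 4, [0.0] * 4, [0.01] * 4))


def test_egger_matches_weighted_regression_with_intercept(rng):
    for L in (10, 25):
        h = random_hset(rng, L)
        a = h.arrays()
        sign = np.where(a["gamma1"] < 0, -1.0, 1.0)
        g, G = a["gamma1"] * sign, a["Gamma"] * sign
        X = sm.add_constant(g)
        fit = sm.WLS(G, X, weights=1.0 / a["se_G"]**2).fit()
        est = egger(h)
        assert est.egger_intercept == pytest.approx(float(fit.params[0]), abs=1e-10)
        assert est.theta == pytest.approx(float(fit.params[1]), abs=1e-10)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def test_weighted_median_middle_element():
    g = np.array([0.1, 0.1, 0.1])
    G = np.array([0.01, 0.02, 0.03])  # ratios 0.1, 0.2, 0.3, equal weights
    est = weighted_median(make_hset(g, [0.01] * 3, G, [0.01] * 3), seed=1)
    assert est.theta == pytest.approx(0.2)


def test_weighted_median_degenerate_ratios(rng):
    g = rng.uniform(0.05, 0.3, 6)
    h = make_hset(g, np.full(6, 1e-4), 0.7 * g, np.full(6, 1e-4))
    est = weighted_median(h, seed=2)
    assert est.theta == pytest.approx(0.7, abs=1e-12)
    assert est.se < 0.05  # bootstrap noise collapses with tiny SEs


def _polyline_median(ratios, weights):
    """Independent evaluation on the sorted cumulative-weight polyline."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    cum = np.concatenate([[0.0], np.cumsum(w)])
    mid = (cum[:-1] + cum[1:]) / 2.0
    for k in range(len(r) - 1):
        if mid[k] <= 0.5 <= mid[k + 1]:
            t = (0.5 - mid[k]) / (mid[k + 1] - mid[k])
            return r[k] + t * (r[k + 1] - r[k])
    return r[0] if 0.5 < mid[0] else r[-1]


def test_weighted_median_matches_polyline_oracle(rng):
    for _ in range(10):
        h = random_hset(rng, 7)
        a = h.arrays()
        est = weighted_median(h, n_boot=10, seed=3)
        expected = _polyline_median(a["Gamma"] / a["gamma1"],
                                    (a["gamma1"] / a["se_G"])**2)
        assert est.theta == pytest.approx(expected, abs=1e-10)


def test_weighted_median_seed_is_mandatory_and_reproducible(rng):
    h = random_hset(rng, 8)
    with pytest.raises(ValueError, match="seed"):
        weighted_median(h)
    assert weighted_median(h, seed=11).se == weighted_median(h, seed=11).se


# ---------------------------------------------------------------------------
# estimator consistency on clean simulated data
# ---------------------------------------------------------------------------

def test_estimators_recover_truth_without_pleiotropy():
    """IVW, Egger slope and weighted median all center on the true effect
    when instruments are strong, effects homogeneous and pleiotropy absent."""
    theta_true = math.log(1.2)
    n_rep = 40
    means = {"ivw": [], "egger": [], "wm": []}
    for s in range(n_rep):
        cfg = SimConfig(seed=900 + s, n_snps=100, rho=0.0, theta1=theta_true,
                        theta2=0.0, r2_target_1=0.05, r2_target_2=0.05)
        study = simulate_summary(cfg)
        h = harmonize(study.exposure1_table, study.outcome_table)
        means["ivw"].append(ivw(h).theta)
        means["egger"].append(egger(h).theta)
        means["wm"].append(weighted_median(h, n_boot=50, seed=s).theta)
    for name, vals in means.items():
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / math.sqrt(n_rep)
        assert abs(vals.mean() - theta_true) < 3 * mc_se + 1e-3, name


# ---------------------------------------------------------------------------
# subgroup heterogeneity
# ---------------------------------------------------------------------------

def test_identical_estimates_have_zero_heterogeneity():
    q, df, p = subgroup_heterogeneity([0.2, 0.2, 0.2], [0.1, 0.2, 0.1])
    assert q == pytest.approx(0.0)
    assert df == 2
    assert p == pytest.approx(1.0)


def test_heterogeneity_matches_hand_sum():
    th = [0.1, 0.3, -0.2]
    se = [0.1, 0.2, 0.15]
    w = [1 / s**2 for s in se]
    pooled = sum(wi * ti for wi, ti in zip(w, th)) / sum(w)
    q_hand = sum(wi * (ti - pooled) ** 2 for wi, ti in zip(w, th))
    q, df, p = subgroup_heterogeneity(th, se)
    assert q == pytest.approx(q_hand, rel=1e-12)
    assert df == 2


def test_heterogeneity_needs_two_finite_estimates():
    with pytest.raises(ValueError):
        subgroup_heterogeneity([0.1], [0.1])
    with pytest.raises(ValueError):
        subgroup_heterogeneity([0.1, 0.2], [0.1, float("inf")])
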