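"""Multivariable MR: direct effects, conditional strength, Q_a."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from directmr.harmonize import harmonize
from directmr.mvmr import (conditional_f, conditional_strength, mvmr_egger,
                           mvmr_ivw, q_a)
from directmr.sumstats import InstrumentSet, SnpAssociation
from directmr.uvmr import ivw

from conftest import make_hset, random_hset


def test_exact_two_exposure_fit_recovered(rng):
    g1 = rng.uniform(0.02, 0.2, 10)
    g2 = rng.uniform(0.02, 0.2, 10)
    G = 0.0 * g1 + 0.3 * g2
    h = make_hset(g1, np.full(10, 0.01), G, np.full(10, 0.01),
                  g2, np.full(10, 0.01))
    fit = mvmr_ivw(h)
    assert fit.theta1 == pytest.approx(0.0, abs=1e-12)
    assert fit.theta2 == pytest.approx(0.3, abs=1e-12)
    q, df, p = q_a(h, fit)
    assert q == pytest.approx(0.0, abs=1e-18)
    assert p == pytest.approx(1.0)


def test_mvmr_matches_two_column_wls_oracle(rng):
    for L in (20, 8):
        h = random_hset(rng, L, two_exposures=True)
        a = h.arrays()
        X = np.column_stack([a["gamma1"], a["gamma2"]])
        fit_sm = sm.WLS(a["Gamma"], X, weights=1.0 / a["se_G"]**2).fit()
        fit = mvmr_ivw(h)
        assert fit.theta1 == pytest.approx(float(fit_sm.params[0]), abs=1e-10)
        assert fit.theta2 == pytest.approx(float(fit_sm.params[1]), abs=1e-10)


def test_mvmr_rank_deficiency_raises(rng):
    g1 = rng.uniform(0.02, 0.2, 6)
    h = make_hset(g1, np.full(6, 0.01), g1 * 0.3, np.full(6, 0.01),
                  2.0 * g1, np.full(6, 0.01))  # gamma2 exactly collinear
    with pytest.raises(ValueError, match="rank"):
        mvmr_ivw(h)


def test_zero_co_exposure_reduces_to_univariable(rng):
    h2 = random_hset(rng, 12, two_exposures=True)
    a = h2.arrays()
    h_zero = make_hset(a["gamma1"], a["se_g1"], a["Gamma"], a["se_G"],
                       np.zeros(12), a["se_g2"])
    h_uni = make_hset(a["gamma1"], a["se_g1"], a["Gamma"], a["se_G"])
    fit = mvmr_ivw(h_zero)
    assert fit.theta1 == pytest.approx(ivw(h_uni).theta, abs=1e-12)
    assert fit.theta2 == 0.0


# ---------------------------------------------------------------------------
# conditional F
# ---------------------------------------------------------------------------

def test_conditional_f_reduces_to_mean_chi2_without_co_signal(rng):
    g1 = rng.uniform(0.02, 0.2, 8)
    se1 = rng.uniform(0.005, 0.02, 8)
    h = make_hset(g1, se1, np.zeros(8), np.full(8, 0.01),
                  np.zeros(8), np.full(8, 0.01))
    f, delta = conditional_f(h, which=1)
    assert delta == 0.0
    assert f == pytest.approx(float(np.sum((g1 / se1) ** 2)) / 7, rel=1e-12)


def test_conditional_f_matches_grid_search_oracle(rng):
    """Profiled Q at the scipy minimiser agrees with a dense delta grid."""
    for _ in range(3):
        h = random_hset(rng, 15, two_exposures=True)
        a = h.arrays()
        f, delta = conditional_f(h, which=1)
        grid = np.arange(-10.0, 10.0001, 1e-4)
        num = (a["gamma1"][None, :] - grid[:, None] * a["gamma2"][None, :]) ** 2
        den = a["se_g1"][None, :] ** 2 + grid[:, None] ** 2 * a["se_g2"][None, :] ** 2
        q_grid = float(np.min(np.sum(num / den, axis=1)))
        assert f * 14 == pytest.approx(q_grid, abs=1e-3)


def test_conditional_f_decreases_with_collinearity(rng):
    """The more correlated the two exposure-beta vectors, the weaker the
    conditional instrument strength."""
    L = 60
    base = rng.normal(0.1, 0.04, L)
    noise = rng.normal(0.0, 0.04, L)
    se = np.full(L, 0.01)
    fs = []
    for mix in (0.0, 0.6, 0.95):
        g2 = mix * base + (1 - mix) * noise
        h = make_hset(base, se, np.zeros(L), np.full(L, 0.01), g2, se)
        fs.append(conditional_f(h, which=1)[0])
    assert fs[0] > fs[1] > fs[2]


def test_phenotypic_correlation_option_changes_denominator(rng):
    h = random_hset(rng, 10, two_exposures=True)
    f0, _ = conditional_f(h, which=1)
    f_corr, _ = conditional_f(h, which=1, phenotypic_correlation=0.8)
    assert f0 != pytest.approx(f_corr)


# ---------------------------------------------------------------------------
# Q_a
# ---------------------------------------------------------------------------

def test_qa_detects_gross_pleiotropic_outlier(rng):
    L = 15
    g1 = rng.uniform(0.05, 0.2, L)
    g2 = rng.uniform(0.05, 0.2, L)
    G = 0.1 * g1 + 0.2 * g2
    G[4] += 0.5  # gross direct SNP->outcome effect
    h = make_hset(g1, np.full(L, 0.005), G, np.full(L, 0.01),
                  g2, np.full(L, 0.005))
    fit = mvmr_ivw(h)
    q, df, p = q_a(h, fit)
    assert df == L - 2
    assert q > stats.chi2.ppf(0.95, df)


def test_qa_matches_term_by_term_sum(rng):
    h = random_hset(rng, 20, two_exposures=True)
    fit = mvmr_ivw(h)
    a = h.arrays()
    acc = 0.0
    for j in range(20):
        r = a["Gamma"][j] - fit.theta1 * a["gamma1"][j] - fit.theta2 * a["gamma2"][j]
        acc += r**2 / (a["se_G"][j]**2 + fit.theta1**2 * a["se_g1"][j]**2
                       + fit.theta2**2 * a["se_g2"][j]**2)
    q, df, p = q_a(h, fit)
    assert q == pytest.approx(acc, rel=1e-12)


# ---------------------------------------------------------------------------
# multivariable MR-Egger
# ---------------------------------------------------------------------------

def test_mvmr_egger_recovers_baked_in_intercept(rng):
    L = 12
    g1 = rng.uniform(0.02, 0.2, L)
    g2 = rng.uniform(0.02, 0.2, L)
    G = 0.02 + 0.1 * g1 + 0.3 * g2  # noiseless with intercept
    h = make_hset(g1, np.full(L, 0.01), G, np.full(L, 0.01), g2, np.full(L, 0.01))
    fit = mvmr_egger(h)
    assert fit.intercept == pytest.approx(0.02, abs=1e-12)
    assert fit.theta1 == pytest.approx(0.1, abs=1e-10)
    assert fit.theta2 == pytest.approx(0.3, abs=1e-10)


def test_mvmr_egger_orientation_symmetric():
    """Flipping the allele coding of one input SNP leaves the fit invariant."""
    def snp(rsid, ea, oa, beta, se=0.01):
        return SnpAssociation(rsid=rsid, effect_allele=ea, other_allele=oa,
                              beta=beta, se=se)

    rng = np.random.default_rng(5)
    L = 8
    g1 = rng.uniform(0.02, 0.2, L)
    g2 = rng.uniform(0.02, 0.2, L)
    G = 0.01 + 0.2 * g1 + 0.1 * g2 + rng.normal(0, 0.005, L)

    def tables(flip_idx=None):
        e1, e2, out = [], [], []
        for j in range(L):
            if j == flip_idx:
                e1.append(snp(f"rs{j}", "G", "A", -g1[j]))
                e2.append(snp(f"rs{j}", "G", "A", -g2[j]))
                out.append(snp(f"rs{j}", "G", "A", -G[j]))
            else:
                e1.append(snp(f"rs{j}", "A", "G", g1[j]))
                e2.append(snp(f"rs{j}", "A", "G", g2[j]))
                out.append(snp(f"rs{j}", "A", "G", G[j]))
        mk = lambda lst, nm: InstrumentSet(exposure_name=nm, associations=lst)
        return mk(e1, "e1"), mk(e2, "e2"), mk(out, "o")

    e1, e2, out = tables()
    ref = mvmr_egger(harmonize([e1, e2], out))
    e1f, e2f, outf = tables(flip_idx=3)
    flipped = mvmr_egger(harmonize([e1f, e2f], outf))
    assert flipped.theta1 == pytest.approx(ref.theta1, abs=1e-12)
    assert flipped.theta2 == pytest.approx(ref.theta2, abs=1e-12)
    assert flipped.intercept == pytest.approx(ref.intercept, abs=1e-12)


def test_mvmr_egger_matches_three_column_wls_oracle(rng):
    h = random_hset(rng, 25, two_exposures=True)
    a = h.arrays()
    sign = np.where(a["gamma1"] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(25), a["gamma1"] * sign, a["gamma2"] * sign])
    fit_sm = sm.WLS(a["Gamma"] * sign, X, weights=1.0 / a["se_G"]**2).fit()
    fit = mvmr_egger(h)
    assert fit.intercept == pytest.approx(float(fit_sm.params[0]), abs=1e-10)
    assert fit.theta1 == pytest.approx(float(fit_sm.params[1]), abs=1e-10)
    assert fit.theta2 == pytest.approx(float(fit_sm.params[2]), abs=1e-10)


def test_conditional_strength_bundle(rng):
    h = random_hset(rng, 20, two_exposures=True)
    cs = conditional_strength(h)
    assert cs.f_cond_1 >= 0 and cs.f_cond_2 >= 0
    assert cs.q_a >= 0 and cs.q_a_df == 18
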