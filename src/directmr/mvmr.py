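"""Multivariable MR: direct effects of two exposures and their diagnostics.

The multivariable IVW fit regresses the outcome betas Gamma_j jointly on the
two exposure betas (gamma1_j, gamma2_j) with weights 1/sigma_Yj² and no
intercept; the coefficients are the direct effects of each exposure holding
the other fixed.  Instrument strength conditional on the co-exposure is
summarised by the conditional F-statistic (a profiled heterogeneity statistic
on the exposure betas), and residual heterogeneity/pleiotropy by Q_a,
referred to chi² with L − 2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .harmonize import HarmonizedSet
from .uvmr import DEFAULT_ALPHA, _normal_ci_p, _orient_positive


@dataclass
class MvmrFit:
    """Direct effects (log-odds per category change) of two exposures."""

    theta1: float
    theta2: float
    se1: float
    se2: float
    ci1_low: float
    ci1_high: float
    ci2_low: float
    ci2_high: float
    pvalue1: float
    pvalue2: float
    n_snp: int
    method: str = "mvmr_ivw"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    @property
    def or1(self) -> float:
        return math.exp(self.theta1)

    @property
    def or2(self) -> float:
        return math.exp(self.theta2)


@dataclass
class ConditionalStrength:
    """Conditional F per exposure and the Q_a pleiotropy statistic."""

    f_cond_1: float
    f_cond_2: float
    delta_1: float
    delta_2: float
    q_a: float
    q_a_df: int
    q_a_pvalue: float


def _require_two_exposures(hset: HarmonizedSet) -> None:
    if hset.n_exposures != 2:
        raise ValueError("multivariable MR needs a two-exposure HarmonizedSet")


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_model: int):
    """Weighted LS coefficients, SEs scaled by max(1, sqrt(RSS_w/df_resid))."""
    L = y.size
    XtW = X.T * w
    A = XtW @ X
    if np.linalg.matrix_rank(A) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear exposure betas)")
    coef = np.linalg.solve(A, XtW @ y)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    df_resid = L - df_model
    scale = max(1.0, math.sqrt(rss_w / df_resid)) if df_resid > 0 else 1.0
    cov = np.linalg.inv(A)
    ses = np.sqrt(np.diag(cov)) * scale
    return coef, ses, rss_w


def mvmr_ivw(hset: HarmonizedSet, alpha: float = DEFAULT_ALPHA) -> MvmrFit:
    """Multivariable IVW: WLS of Gamma on (gamma1, gamma2), no intercept."""
    _require_two_exposures(hset)
    L = hset.L
    if L < 3:
        raise ValueError(f"multivariable IVW needs at least 3 SNPs, got {L}")
    a = hset.arrays()
    w = 1.0 / a["se_G"]**2
    for this, other in ((1, 2), (2, 1)):
        # a co-exposure with no instrument signal contributes nothing: the
        # fit reduces to univariable IVW on the remaining exposure
        if np.all(a[f"gamma{other}"] == 0):
            g, G = a[f"gamma{this}"], a["Gamma"]
            coef_u, ses_u, _ = _wls(g[:, None], G, w, df_model=1)
            theta, se = float(coef_u[0]), float(ses_u[0])
            lo, hi, p = _normal_ci_p(theta, se, alpha)
            inf = float("inf")
            pair = dict(theta1=theta, theta2=0.0, se1=se, se2=inf,
                        ci1_low=lo, ci1_high=hi, ci2_low=-inf, ci2_high=inf,
                        pvalue1=p, pvalue2=1.0)
            if this == 2:
                pair = dict(theta1=0.0, theta2=theta, se1=inf, se2=se,
                            ci1_low=-inf, ci1_high=inf, ci2_low=lo, ci2_high=hi,
                            pvalue1=1.0, pvalue2=p)
            return MvmrFit(n_snp=L, method="mvmr_ivw", **pair)
    X = np.column_stack([a["gamma1"], a["gamma2"]])
    coef, ses, _ = _wls(X, a["Gamma"], w, df_model=2)
    lo1, hi1, p1 = _normal_ci_p(coef[0], ses[0], alpha)
    lo2, hi2, p2 = _normal_ci_p(coef[1], ses[1], alpha)
    return MvmrFit(theta1=float(coef[0]), theta2=float(coef[1]),
                   se1=float(ses[0]), se2=float(ses[1]),
                   ci1_low=lo1, ci1_high=hi1, ci2_low=lo2, ci2_high=hi2,
                   pvalue1=p1, pvalue2=p2, n_snp=L, method="mvmr_ivw")


def mvmr_egger(hset: HarmonizedSet, alpha: float = DEFAULT_ALPHA) -> MvmrFit:
    """Multivariable MR-Egger: as mvmr_ivw with a free intercept.

    Records are oriented so all gamma1 are positive; the intercept test is
    the multivariable directional-pleiotropy diagnostic, and the slopes are
    pleiotropy-adjusted direct effects.  Residual df is L − 3.
    """
    _require_two_exposures(hset)
    L = hset.L
    if L < 4:
        raise ValueError(f"multivariable MR-Egger needs at least 4 SNPs, got {L}")
    a = hset.arrays()
    sign = np.where(a["gamma1"] < 0, -1.0, 1.0)
    g1, g2, G = a["gamma1"] * sign, a["gamma2"] * sign, a["Gamma"] * sign
    X = np.column_stack([np.ones(L), g1, g2])
    w = 1.0 / a["se_G"]**2
    coef, ses, _ = _wls(X, G, w, df_model=3)
    lo1, hi1, p1 = _normal_ci_p(coef[1], ses[1], alpha)
    lo2, hi2, p2 = _normal_ci_p(coef[2], ses[2], alpha)
    _, _, p0 = _normal_ci_p(coef[0], ses[0], alpha)
    return MvmrFit(theta1=float(coef[1]), theta2=float(coef[2]),
                   se1=float(ses[1]), se2=float(ses[2]),
                   ci1_low=lo1, ci1_high=hi1, ci2_low=lo2, ci2_high=hi2,
                   pvalue1=p1, pvalue2=p2, n_snp=L, method="mvmr_egger",
                   intercept=float(coef[0]), intercept_se=float(ses[0]),
                   intercept_pvalue=p0)


def conditional_f(
    hset: HarmonizedSet,
    which: int = 1,
    cross_cov: "float | np.ndarray" = 0.0,
    phenotypic_correlation: float | None = None,
    bounds: tuple[float, float] = (-100.0, 100.0),
    xatol: float = 1e-8,
) -> tuple[float, float]:
    """Conditional F-statistic for one exposure given the other.

    Profiles the nuisance slope delta in
    Q_x(delta) = sum_j (g_j − delta h_j)² / (se_g_j² + delta² se_h_j² −
    2 delta cov_j) by bounded scalar minimisation; F = Q_x(delta_hat)/(L−1).
    ``cross_cov`` gives the per-SNP sampling covariance between the two
    exposure betas (0 by default); alternatively
    ``phenotypic_correlation`` r populates cov_j = r se_g_j se_h_j, the usual
    choice when both exposures were measured in the same sample.
    """
    _require_two_exposures(hset)
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    L = hset.L
    if L < 2:
        raise ValueError("conditional F needs at least 2 SNPs")
    a = hset.arrays()
    if which == 1:
        g, se_g, h, se_h = a["gamma1"], a["se_g1"], a["gamma2"], a["se_g2"]
    else:
        g, se_g, h, se_h = a["gamma2"], a["se_g2"], a["gamma1"], a["se_g1"]
    if phenotypic_correlation is not None:
        cov = phenotypic_correlation * se_g * se_h
    else:
        cov = np.broadcast_to(np.asarray(cross_cov, dtype=float), g.shape)

    if np.all(h == 0):
        # delta is unidentified without co-exposure signal; no adjustment is
        # possible and the statistic reduces to the unconditional mean chi²
        return float(np.sum((g / se_g) ** 2)) / (L - 1), 0.0

    def q_x(delta: float) -> float:
        denom = se_g**2 + delta**2 * se_h**2 - 2.0 * delta * cov
        if np.any(denom <= 0):
            return np.inf
        return float(np.sum((g - delta * h) ** 2 / denom))

    res = optimize.minimize_scalar(q_x, bounds=bounds, method="bounded",
                                   options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"conditional-F delta minimisation failed: {res.message}")
    return float(res.fun) / (L - 1), float(res.x)


def q_a(hset: HarmonizedSet, fit: MvmrFit) -> tuple[float, int, float]:
    """Multivariable heterogeneity statistic Q_a against chi²_{L−2}.

    Q_a = sum_j (Gamma_j − theta1 g1j − theta2 g2j)² /
          (se_G_j² + theta1² se_g1_j² + theta2² se_g2_j²).
    """
    _require_two_exposures(hset)
    a = hset.arrays()
    resid = a["Gamma"] - fit.theta1 * a["gamma1"] - fit.theta2 * a["gamma2"]
    denom = a["se_G"]**2 + fit.theta1**2 * a["se_g1"]**2 + fit.theta2**2 * a["se_g2"]**2
    q = float(np.sum(resid**2 / denom))
    df = hset.L - 2
    return q, df, float(stats.chi2.sf(q, df))


def conditional_strength(
    hset: HarmonizedSet,
    fit: MvmrFit | None = None,
    phenotypic_correlation: float | None = None,
) -> ConditionalStrength:
    """Bundle conditional F for both exposures with Q_a for a fit."""
    f1, d1 = conditional_f(hset, 1, phenotypic_correlation=phenotypic_correlation)
    f2, d2 = conditional_f(hset, 2, phenotypic_correlation=phenotypic_correlation)
    if fit is None:
        fit = mvmr_ivw(hset)
    q, df, p = q_a(hset, fit)
    return ConditionalStrength(f_cond_1=f1, f_cond_2=f2, delta_1=d1, delta_2=d2,
                               q_a=q, q_a_df=df, q_a_pvalue=p)
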