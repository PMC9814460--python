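"""Univariable two-sample MR estimators and heterogeneity statistics.

All estimators take a :class:`~directmr.harmonize.HarmonizedSet` of
SNP-aligned exposure betas gamma_j (SE sigma_xj) and outcome log-odds
Gamma_j (SE sigma_Yj) and return an :class:`MrEstimate` on the log-odds
(theta) scale with the exponentiated odds-ratio alongside.

The inverse-variance-weighted (IVW) estimator is the weighted regression of
Gamma on gamma through the origin with weights 1/sigma_Yj²; Cochran's Q on
the per-SNP Wald ratios diagnoses heterogeneity, and in the multiplicative
random-effects mode the fixed-effect SE is inflated by
sqrt(max(1, Q/(L−1))).  MR-Egger frees the intercept (its test is the
directional-pleiotropy diagnostic) and the weighted median interpolates the
per-SNP ratio at cumulative weight 0.5, with a parametric-bootstrap SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedRecord, HarmonizedSet

DEFAULT_ALPHA = 0.05


@dataclass
class MrEstimate:
    """A method-tagged causal estimate with diagnostics.

    ``theta`` is the causal log-odds change per category change of the
    exposure; ``or_`` = exp(theta).  Heterogeneity (Cochran's Q) and Egger
    intercept fields are populated only where the method defines them.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None
    exposure: str = ""
    outcome: str = ""
    stratum: str = ""

    @property
    def or_(self) -> float:
        return math.exp(self.theta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    @property
    def beta(self) -> float:  # result-table alias
        return self.theta


def _normal_ci_p(theta: float, se: float, alpha: float) -> tuple[float, float, float]:
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = 2.0 * stats.norm.sf(abs(theta) / se) if se > 0 else float(theta == 0.0)
    return theta - z * se, theta + z * se, p


def wald_ratio(record: HarmonizedRecord, alpha: float = DEFAULT_ALPHA) -> MrEstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order SE se_G/|gamma|."""
    if record.gamma1 == 0:
        raise ValueError(f"{record.rsid}: zero exposure beta, Wald ratio undefined")
    theta = record.Gamma / record.gamma1
    se = record.se_G / abs(record.gamma1)
    lo, hi, p = _normal_ci_p(theta, se, alpha)
    return MrEstimate(method="wald", theta=theta, se=se, ci_low=lo, ci_high=hi,
                      pvalue=p, n_snp=1)


def ivw(hset: HarmonizedSet, mode: str = "auto", alpha: float = DEFAULT_ALPHA) -> MrEstimate:
    """Inverse-variance-weighted estimate (fixed / multiplicative-random / auto).

    The point estimate is identical in every mode.  ``auto`` reports the
    fixed-effect SE unless Cochran's Q is significant at 0.05, in which case
    the multiplicative random-effects SE is used.
    """
    if mode not in {"auto", "fixed", "random"}:
        raise ValueError(f"unknown IVW mode {mode!r}")
    a = hset.arrays()
    g, G, se_G = a["gamma1"], a["Gamma"], a["se_G"]
    w = 1.0 / se_G**2
    denom = float(np.sum(w * g * g))
    theta = float(np.sum(w * g * G)) / denom
    se_fixed = denom ** -0.5

    L = hset.L
    q_stat = q_pvalue = None
    q_df = None
    scale = 1.0
    use_random = mode == "random"
    if L >= 2:
        q_stat = float(np.sum(w * (G - theta * g) ** 2))
        q_df = L - 1
        q_pvalue = float(stats.chi2.sf(q_stat, q_df))
        use_random = mode == "random" or (mode == "auto" and q_pvalue < 0.05)
        if use_random:
            scale = max(1.0, math.sqrt(q_stat / q_df))
    se = se_fixed * scale
    lo, hi, p = _normal_ci_p(theta, se, alpha)
    method = "ivw_random" if use_random else "ivw_fixed"
    return MrEstimate(method=method, theta=theta, se=se, ci_low=lo, ci_high=hi,
                      pvalue=p, n_snp=L, q_stat=q_stat, q_df=q_df, q_pvalue=q_pvalue)


def _orient_positive(g, G, se_G, se_g=None):
    """Flip records so every exposure beta is positive (Egger convention)."""
    sign = np.where(g < 0, -1.0, 1.0)
    out = (g * sign, G * sign, se_G)
    return out if se_g is None else out + (se_g,)


def egger(hset: HarmonizedSet, alpha: float = DEFAULT_ALPHA) -> MrEstimate:
    """MR-Egger: weighted regression of Gamma on gamma with free intercept.

    Records are oriented so all exposure betas are positive.  SEs of slope
    and intercept are inflated by sqrt(max(1, Q_egger/(L−2))); the intercept
    p-value is the directional-pleiotropy test.
    """
    L = hset.L
    if L < 3:
        raise ValueError(f"MR-Egger needs at least 3 SNPs, got {L}")
    a = hset.arrays()
    g, G, se_G = _orient_positive(a["gamma1"], a["Gamma"], a["se_G"])
    if np.allclose(g, g[0]):
        raise ValueError("degenerate design: all exposure betas equal")
    w = 1.0 / se_G**2
    X = np.column_stack([np.ones(L), g])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], G * sw, rcond=None)
    b0, b1 = float(coef[0]), float(coef[1])
    resid = G - (b0 + b1 * g)
    q_egger = float(np.sum(w * resid**2))
    q_df = L - 2
    scale = max(1.0, math.sqrt(q_egger / q_df))
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    se_b0 = math.sqrt(cov[0, 0]) * scale
    se_b1 = math.sqrt(cov[1, 1]) * scale
    lo, hi, p = _normal_ci_p(b1, se_b1, alpha)
    _, _, p0 = _normal_ci_p(b0, se_b0, alpha)
    return MrEstimate(
        method="egger", theta=b1, se=se_b1, ci_low=lo, ci_high=hi, pvalue=p,
        n_snp=L, q_stat=q_egger, q_df=q_df, q_pvalue=float(stats.chi2.sf(q_egger, q_df)),
        egger_intercept=b0, egger_intercept_se=se_b0, egger_intercept_pvalue=p0)


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative midpoint polyline at p=0.5."""
    order = np.argsort(theta)
    th, wt = theta[order], w[order]
    wt = wt / wt.sum()
    midpoints = np.cumsum(wt) - wt / 2.0
    return float(np.interp(0.5, midpoints, th))


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP ratios Gamma/gamma weighted by (gamma/se_G)²; consistent when up
    to half the instrument weight comes from invalid instruments.  The SE
    resamples gamma and Gamma from normal distributions centred on their
    estimates (``seed`` is mandatory for reproducibility).
    """
    L = hset.L
    if L < 3:
        raise ValueError(f"weighted median needs at least 3 SNPs, got {L}")
    if seed is None:
        raise ValueError("weighted_median requires an explicit bootstrap seed")
    a = hset.arrays()
    g, se_g, G, se_G = a["gamma1"], a["se_g1"], a["Gamma"], a["se_G"]
    ratios = G / g
    w = (g / se_G) ** 2
    theta = _weighted_median(ratios, w)

    rng = np.random.default_rng(seed)
    g_b = rng.normal(g, se_g, size=(n_boot, L))
    G_b = rng.normal(G, se_G, size=(n_boot, L))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = _weighted_median(G_b[i] / g_b[i], (g_b[i] / se_G) ** 2)
    se = float(np.std(boot, ddof=1))
    lo, hi, p = _normal_ci_p(theta, se, alpha)
    return MrEstimate(method="weighted_median", theta=theta, se=se,
                      ci_low=lo, ci_high=hi, pvalue=p, n_snp=L)


def subgroup_heterogeneity(
    thetas: "list[float] | list[MrEstimate]",
    ses: list[float] | None = None,
) -> tuple[float, int, float]:
    """Cochran-type heterogeneity across strata (sex, anatomical subsite).

    Accepts either a list of MrEstimates or parallel theta/SE lists.
    Returns (Q, df, p) with Q = sum (theta_s − pooled)²/se_s², df = S − 1.
    """
    if ses is None:
        ests = thetas
        th = np.array([e.theta for e in ests], dtype=float)
        se = np.array([e.se for e in ests], dtype=float)
    else:
        th = np.asarray(thetas, dtype=float)
        se = np.asarray(ses, dtype=float)
    if th.size < 2:
        raise ValueError("subgroup heterogeneity needs at least 2 estimates")
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all standard errors must be finite and positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * th) / np.sum(w))
    q = float(np.sum(w * (th - pooled) ** 2))
    df = th.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def se_from_ci(or_low: float, or_high: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Back-compute a log-odds SE from a printed OR confidence interval."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return (math.log(or_high) - math.log(or_low)) / (2.0 * z)
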