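"""Synthetic two-sample GWAS summary statistics with known causal truth.

Emulates the structure of a body-size → colorectal-cancer MR study: two
genetically correlated category-scale exposures (true per-SNP effects drawn
bivariate-normal, correlation ``rho``, default 0.61), instruments scaled so
they explain a configured fraction of each exposure's variance, an outcome
generated from per-category direct log-odds effects of both exposures plus
optional pleiotropic SNP effects, and sampling noise matching a
453,169-person exposure GWAS and a 52,775-case / 45,940-control outcome
GWAS.

Two generation paths share one :class:`SimConfig`:

* :func:`simulate_summary` draws observed betas directly around their true
  values with analytic standard errors — fast, used for estimator studies.
* :func:`simulate_individual` simulates genotypes and individuals, cuts a
  latent continuous trait into three ordered body-size categories, runs the
  exposure and outcome GWAS regressions, and emits the resulting summary
  tables — the slow oracle path used to validate the fast path and the
  analytic power formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import InstrumentSet, SnpAssociation

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("C", "T"), ("G", "T"),
                 ("A", "T"), ("C", "G")]  # includes palindromic pairs

#: fields of the truth record emitted alongside the tables
TRUTH_COLUMNS = ("rsid", "maf", "g1_true", "g2_true", "pleio", "Gamma_true")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated two-sample MR study.

    Defaults mirror the motivating study: ~305-SNP instrument, effect
    correlation 0.61, instruments explaining 4.5% / 6.4% of the two
    exposures, exposure GWAS of 453,169, outcome sample of 52,775 cases and
    45,940 controls, a true early-life direct effect of zero and an adult
    direct effect of ln(1.3) per category change.
    """

    seed: int
    n_snps: int = 305
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.61
    theta1: float = 0.0
    theta2: float = math.log(1.3)
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    n_exposure_gwas: int = 453_169
    n_cases: int = 52_775
    n_controls: int = 45_940
    r2_target_1: float = 0.045
    r2_target_2: float = 0.064
    category_cuts: tuple[float, float] = (0.25, 0.75)
    #: report exposure GWAS betas per SD of the category variable instead of
    #: per category — the scale on which the analytic power formula (which
    #: assumes a unit-variance exposure) is defined
    standardize_exposure: bool = False

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if min(self.n_exposure_gwas, self.n_cases, self.n_controls) <= 0:
            raise ValueError("sample sizes must be positive")
        for r2 in (self.r2_target_1, self.r2_target_2):
            if not 0.0 < r2 < 1.0:
                raise ValueError(f"r² targets must lie in (0, 1), got {r2}")
        if not 0.0 < self.category_cuts[0] < self.category_cuts[1] < 1.0:
            raise ValueError(f"category cuts must be ordered in (0,1), got {self.category_cuts}")


@dataclass
class SimulatedStudy:
    exposure1_table: InstrumentSet
    exposure2_table: InstrumentSet
    outcome_table: InstrumentSet
    truth: pd.DataFrame
    config: SimConfig


def category_moments(cuts: tuple[float, float]) -> tuple[float, float]:
    """(slope, variance) of the 0/1/2 category variable against a N(0,1) latent.

    slope = cov(latent, category) = sum of the normal density at the cut
    z-scores; variance from the category probabilities.  With the default
    25/75 cuts the slope is ~0.636 and the variance 0.5.
    """
    thresholds = stats.norm.ppf(cuts)
    slope = float(np.sum(stats.norm.pdf(thresholds)))
    probs = np.diff([0.0, *cuts, 1.0])
    values = np.arange(len(probs), dtype=float)
    mean = float(np.sum(values * probs))
    var = float(np.sum(values**2 * probs) - mean**2)
    return slope, var


def _draw_snps(config: SimConfig) -> tuple[np.ndarray, list[tuple[str, str]], list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Shared layer: maf, alleles, rsids and true category-scale effects.

    True per-SNP effects on the two exposures are bivariate normal with
    correlation rho, rescaled so each instrument explains exactly its r²
    target of a trait with the category variance, then oriented so the
    effect allele increases exposure 1.
    """
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_snps
    maf = rng.uniform(*config.maf_range, size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]
    rsids = [f"rs{i + 1}" for i in range(n)]

    cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
    u = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    het = 2.0 * maf * (1.0 - maf)
    _, var_c = category_moments(config.category_cuts)
    g1 = u[:, 0] * math.sqrt(config.r2_target_1 * var_c / float(np.sum(het * u[:, 0] ** 2)))
    g2 = u[:, 1] * math.sqrt(config.r2_target_2 * var_c / float(np.sum(het * u[:, 1] ** 2)))
    # orient so the effect allele is exposure-1-increasing
    sign = np.where(g1 < 0, -1.0, 1.0)
    g1, g2 = g1 * sign, g2 * sign

    if config.pleio_sd > 0 or config.pleio_mean != 0:
        pleio_rng = np.random.default_rng([config.seed, 202])
        pleio = pleio_rng.normal(config.pleio_mean, config.pleio_sd, size=n)
    else:
        pleio = np.zeros(n)
    return maf, alleles, rsids, g1, g2, pleio


def _truth_frame(rsids, maf, g1, g2, pleio, gamma_true) -> pd.DataFrame:
    return pd.DataFrame({
        "rsid": rsids, "maf": maf, "g1_true": g1, "g2_true": g2,
        "pleio": pleio, "Gamma_true": gamma_true,
    }, columns=list(TRUTH_COLUMNS))


def _build_table(rsids, alleles, maf, beta, se, n, name, r_squared=None) -> InstrumentSet:
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    assocs = [
        SnpAssociation(rsid=r, effect_allele=ea, other_allele=oa,
                       eaf=float(f), beta=float(b), se=float(s),
                       pvalue=float(p), n=float(n))
        for r, (ea, oa), f, b, s, p in zip(rsids, alleles, maf, beta, se, pvals)
    ]
    return InstrumentSet(exposure_name=name, associations=assocs,
                         r_squared=r_squared, n_gwas=n)


def simulate_summary(config: SimConfig) -> SimulatedStudy:
    """Fast path: observed betas drawn around truth with analytic SEs.

    Exposure-beta SE is sqrt(var_c / (2 maf (1−maf) N_exp)); the outcome
    log-odds SE uses the standard case-control approximation
    sqrt((1/n_cases + 1/n_controls) / (2 maf (1−maf))).  Identical seed and
    config give identical output.
    """
    config.validate()
    maf, alleles, rsids, g1, g2, pleio = _draw_snps(config)
    het = 2.0 * maf * (1.0 - maf)
    _, var_c = category_moments(config.category_cuts)
    gamma_true = config.theta1 * g1 + config.theta2 * g2 + pleio

    se1 = np.sqrt(var_c / (het * config.n_exposure_gwas))
    se2 = np.sqrt(var_c / (het * config.n_exposure_gwas))
    se_out = np.sqrt((1.0 / config.n_cases + 1.0 / config.n_controls) / het)

    rng = np.random.default_rng([config.seed, 303])
    beta1 = rng.normal(g1, se1)
    beta2 = rng.normal(g2, se2)
    beta_out = rng.normal(gamma_true, se_out)

    n_out = config.n_cases + config.n_controls
    return SimulatedStudy(
        exposure1_table=_build_table(rsids, alleles, maf, beta1, se1,
                                     config.n_exposure_gwas, "exposure1",
                                     config.r2_target_1),
        exposure2_table=_build_table(rsids, alleles, maf, beta2, se2,
                                     config.n_exposure_gwas, "exposure2",
                                     config.r2_target_2),
        outcome_table=_build_table(rsids, alleles, maf, beta_out, se_out,
                                   n_out, "outcome"),
        truth=_truth_frame(rsids, maf, g1, g2, pleio, gamma_true),
        config=config,
    )


MAX_INDIVIDUALS = 1_000_000  # desk guard for the individual-level path


def _ols_per_snp(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Simple-regression slope and SE of y on each column of x (vectorised)."""
    n = y.size
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc * xc, axis=0)
    sxy = xc.T @ yc
    beta = sxy / sxx
    syy = float(np.sum(yc * yc))
    rss = syy - beta * sxy
    se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
    return beta, se


def _logistic_score_per_snp(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-step (score) per-SNP logistic log-odds estimate and SE.

    The Newton step from the null model — the standard fast GWAS
    approximation, accurate for the small per-allele effects simulated here.
    """
    ybar = y.mean()
    xc = x - x.mean(axis=0)
    score = xc.T @ (y - ybar)
    info = ybar * (1.0 - ybar) * np.sum(xc * xc, axis=0)
    return score / info, 1.0 / np.sqrt(info)


def simulate_individual(config: SimConfig) -> SimulatedStudy:
    """Slow oracle path: genotypes, latent traits, categories, GWAS fits.

    Exposure sample: genotypes Binomial(2, maf); latent trait = genotype
    score + normal noise, standardised to unit variance; body-size category
    obtained by cutting the latent at the configured quantiles; per-SNP OLS
    of category on genotype gives the exposure tables.  Outcome sample
    (independent): case status from a logistic model with the configured
    per-category direct effects and per-allele pleiotropic effects; per-SNP
    score-based logistic regression gives the outcome table.
    """
    config.validate()
    n_out = config.n_cases + config.n_controls
    if config.n_exposure_gwas + n_out > MAX_INDIVIDUALS:
        raise ValueError(
            f"individual-level path capped at {MAX_INDIVIDUALS} individuals; "
            f"requested {config.n_exposure_gwas + n_out}")
    maf, alleles, rsids, g1, g2, pleio = _draw_snps(config)
    lam, var_c = category_moments(config.category_cuts)
    # category-scale effects g are lam * latent-scale effects
    a1, a2 = g1 / lam, g2 / lam
    het = 2.0 * maf * (1.0 - maf)
    var_score_1 = float(np.sum(het * a1**2))
    var_score_2 = float(np.sum(het * a2**2))
    if max(var_score_1, var_score_2) >= 1.0:
        raise ValueError("infeasible r² target: latent genetic variance ≥ 1")
    thresholds = stats.norm.ppf(config.category_cuts)

    def categories(x: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        center = 2.0 * maf
        z1 = (x - center) @ a1 + rng.normal(0.0, math.sqrt(1.0 - var_score_1), size=x.shape[0])
        z2 = (x - center) @ a2 + rng.normal(0.0, math.sqrt(1.0 - var_score_2), size=x.shape[0])
        c1 = np.searchsorted(thresholds, z1).astype(float)
        c2 = np.searchsorted(thresholds, z2).astype(float)
        return c1, c2

    # exposure sample
    rng_e = np.random.default_rng([config.seed, 404])
    x_e = rng_e.binomial(2, maf, size=(config.n_exposure_gwas, config.n_snps)).astype(float)
    c1_e, c2_e = categories(x_e, rng_e)
    if config.standardize_exposure:
        sd_c = math.sqrt(var_c)
        c1_e, c2_e = c1_e / sd_c, c2_e / sd_c
    beta1, se1 = _ols_per_snp(x_e, c1_e)
    beta2, se2 = _ols_per_snp(x_e, c2_e)

    # outcome sample (case-control; intercept set for the target case fraction)
    rng_o = np.random.default_rng([config.seed, 505])
    x_o = rng_o.binomial(2, maf, size=(n_out, config.n_snps)).astype(float)
    c1_o, c2_o = categories(x_o, rng_o)
    k = config.n_cases / n_out
    probs = np.diff([0.0, *config.category_cuts, 1.0])
    mean_c = float(np.sum(np.arange(len(probs)) * probs))  # =1 for 25/75 cuts
    b0 = (math.log(k / (1.0 - k)) - config.theta1 * mean_c - config.theta2 * mean_c
          - float(np.sum(pleio * 2.0 * maf)))
    logit = b0 + config.theta1 * c1_o + config.theta2 * c2_o + x_o @ pleio
    y = (rng_o.random(n_out) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
    beta_out, se_out = _logistic_score_per_snp(x_o, y)

    gamma_true = config.theta1 * g1 + config.theta2 * g2 + pleio
    return SimulatedStudy(
        exposure1_table=_build_table(rsids, alleles, maf, beta1, se1,
                                     config.n_exposure_gwas, "exposure1",
                                     config.r2_target_1),
        exposure2_table=_build_table(rsids, alleles, maf, beta2, se2,
                                     config.n_exposure_gwas, "exposure2",
                                     config.r2_target_2),
        outcome_table=_build_table(rsids, alleles, maf, beta_out, se_out,
                                   n_out, "outcome"),
        truth=_truth_frame(rsids, maf, g1, g2, pleio, gamma_true),
        config=config,
    )
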