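"""Orchestration of the full analysis grid from a configuration file.

Runs every exposure × outcome × stratum cell of the univariable analysis
(IVW in auto mode, MR-Egger, weighted median, instrument strength), the
multivariable grid (MVMR-IVW, conditional F for both exposures, Q_a,
MVMR-Egger) and the a-priori power report.  Cells fail independently: one
malformed table is reported without aborting the rest of the grid, and every
output row carries the configuration hash and seed for provenance.

No multiple-testing adjustment is applied anywhere; the grids report raw
per-cell p-values.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mvmr as mv
from . import uvmr as uv
from .harmonize import harmonize
from .instruments import strength_report
from .power import power_grid
from .simulate import category_moments
from .sumstats import InstrumentSet, read_associations

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Paths and flags for one full analysis run.

    ``exposures`` / ``outcomes`` map name → stratum → TSV path.
    ``mvmr_exposures`` optionally maps the two exposure names to the
    multivariable SNP-set tables (falls back to ``exposures``).
    ``power_cells`` maps "outcome/stratum" → {n_cases, n_controls} and
    ``r_squared`` maps exposure name → instrument variance explained.
    """

    exposures: dict[str, dict[str, str]]
    outcomes: dict[str, dict[str, str]]
    mvmr_exposures: dict[str, dict[str, str]] | None = None
    power_cells: dict[str, dict[str, int]] = field(default_factory=dict)
    r_squared: dict[str, float] = field(default_factory=dict)
    column_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    n_boot: int = 1000
    alpha: float = 0.05
    ivw_mode: str = "auto"
    strict_palindromes: bool = False
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def digest(self) -> str:
        canon = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _load_tables(spec: dict[str, dict[str, str]], column_map) -> dict[str, dict[str, InstrumentSet]]:
    loaded: dict[str, dict[str, InstrumentSet]] = {}
    for name, strata in spec.items():
        loaded[name] = {
            stratum: read_associations(path, column_map=column_map,
                                       exposure_name=name, stratum=stratum)
            for stratum, path in strata.items()
        }
    return loaded


def _provenance(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    df["config_hash"] = config.digest()
    df["seed"] = config.seed
    return df


def run_univariable_grid(
    config: AnalysisConfig,
    exposures: dict[str, dict[str, InstrumentSet]] | None = None,
    outcomes: dict[str, dict[str, InstrumentSet]] | None = None,
) -> pd.DataFrame:
    """Total-effect estimates for every exposure × outcome × stratum cell.

    Tables may be passed in memory (tests, simulations) or loaded from the
    configured paths.  Returns one row per estimator per cell; failed cells
    appear with an ``error`` message instead of estimates.
    """
    exposures = exposures if exposures is not None else _load_tables(config.exposures, config.column_map)
    outcomes = outcomes if outcomes is not None else _load_tables(config.outcomes, config.column_map)
    _, var_c = category_moments((0.25, 0.75))
    rows: list[dict] = []
    for exp_name, exp_strata in exposures.items():
        for out_name, out_strata in outcomes.items():
            for stratum in exp_strata:
                if stratum not in out_strata:
                    continue
                cell = f"{exp_name}|{out_name}|{stratum}"
                try:
                    hset = harmonize(exp_strata[stratum], out_strata[stratum],
                                     strict_palindromes=config.strict_palindromes)
                    estimates = [uv.ivw(hset, mode=config.ivw_mode, alpha=config.alpha)]
                    if hset.L >= 3:
                        estimates.append(uv.egger(hset, alpha=config.alpha))
                        estimates.append(uv.weighted_median(
                            hset, n_boot=config.n_boot,
                            seed=config.seed, alpha=config.alpha))
                    min_f = None
                    if all(a.eaf is not None for a in exp_strata[stratum]) \
                            and exp_strata[stratum].n_gwas is not None:
                        min_f = strength_report(exp_strata[stratum],
                                                var_trait=var_c).min_f
                    for est in estimates:
                        est.exposure, est.outcome, est.stratum = exp_name, out_name, stratum
                        rows.append({
                            "exposure": exp_name, "outcome": out_name,
                            "stratum": stratum, "method": est.method,
                            "n_snp": est.n_snp, "beta": est.theta, "se": est.se,
                            "or_": est.or_, "ci_low": est.ci_low,
                            "ci_high": est.ci_high, "pvalue": est.pvalue,
                            "q_stat": est.q_stat, "q_df": est.q_df,
                            "q_pvalue": est.q_pvalue,
                            "egger_intercept": est.egger_intercept,
                            "egger_intercept_se": est.egger_intercept_se,
                            "egger_intercept_pvalue": est.egger_intercept_pvalue,
                            "min_f": min_f, "error": None,
                        })
                except Exception as exc:  # cell-isolated failure
                    logger.error("[%s] univariable cell failed: %s", cell, exc)
                    rows.append({"exposure": exp_name, "outcome": out_name,
                                 "stratum": stratum, "method": None,
                                 "error": str(exc)})
    return _provenance(pd.DataFrame(rows), config)


def run_multivariable_grid(
    config: AnalysisConfig,
    exposures: dict[str, dict[str, InstrumentSet]] | None = None,
    outcomes: dict[str, dict[str, InstrumentSet]] | None = None,
) -> pd.DataFrame:
    """Direct-effect estimates per outcome × stratum, with diagnostics.

    Requires exactly two exposures sharing each stratum's SNP set (the
    multivariable instrument tables when configured).  Appends a
    men-vs-women heterogeneity row per outcome and exposure when both sex
    strata succeeded.
    """
    spec = config.mvmr_exposures or config.exposures
    exposures = exposures if exposures is not None else _load_tables(spec, config.column_map)
    outcomes = outcomes if outcomes is not None else _load_tables(config.outcomes, config.column_map)
    names = list(exposures)
    if len(names) != 2:
        raise ValueError(f"multivariable grid needs exactly 2 exposures, got {names}")
    e1_name, e2_name = names

    rows: list[dict] = []
    sex_fits: dict[tuple[str, str], mv.MvmrFit] = {}
    for out_name, out_strata in outcomes.items():
        for stratum in out_strata:
            if stratum not in exposures[e1_name] or stratum not in exposures[e2_name]:
                continue
            cell = f"{out_name}|{stratum}"
            try:
                hset = harmonize(
                    [exposures[e1_name][stratum], exposures[e2_name][stratum]],
                    out_strata[stratum],
                    strict_palindromes=config.strict_palindromes)
                fit = mv.mvmr_ivw(hset, alpha=config.alpha)
                strength = mv.conditional_strength(hset, fit)
                egger_fit = mv.mvmr_egger(hset, alpha=config.alpha) if hset.L >= 4 else None
                sex_fits[(out_name, stratum)] = fit
                for which, exp_name in ((1, e1_name), (2, e2_name)):
                    theta = fit.theta1 if which == 1 else fit.theta2
                    se = fit.se1 if which == 1 else fit.se2
                    rows.append({
                        "outcome": out_name, "stratum": stratum,
                        "exposure": exp_name, "method": "mvmr_ivw",
                        "n_snp": fit.n_snp, "beta": theta, "se": se,
                        "or_": math.exp(theta),
                        "ci_low": fit.ci1_low if which == 1 else fit.ci2_low,
                        "ci_high": fit.ci1_high if which == 1 else fit.ci2_high,
                        "pvalue": fit.pvalue1 if which == 1 else fit.pvalue2,
                        "f_cond": strength.f_cond_1 if which == 1 else strength.f_cond_2,
                        "q_a": strength.q_a, "q_a_df": strength.q_a_df,
                        "q_a_pvalue": strength.q_a_pvalue,
                        "egger_beta": None if egger_fit is None else
                            (egger_fit.theta1 if which == 1 else egger_fit.theta2),
                        "egger_se": None if egger_fit is None else
                            (egger_fit.se1 if which == 1 else egger_fit.se2),
                        "egger_intercept": None if egger_fit is None else egger_fit.intercept,
                        "egger_intercept_pvalue": None if egger_fit is None else egger_fit.intercept_pvalue,
                        "error": None,
                    })
            except Exception as exc:
                logger.error("[%s] multivariable cell failed: %s", cell, exc)
                rows.append({"outcome": out_name, "stratum": stratum,
                             "exposure": None, "method": None, "error": str(exc)})

        # sex heterogeneity of the direct effects, when both sexes ran
        if (out_name, "men") in sex_fits and (out_name, "women") in sex_fits:
            men, women = sex_fits[(out_name, "men")], sex_fits[(out_name, "women")]
            for exp_name, thetas, ses in (
                (e1_name, (men.theta1, women.theta1), (men.se1, women.se1)),
                (e2_name, (men.theta2, women.theta2), (men.se2, women.se2)),
            ):
                q, df, p = uv.subgroup_heterogeneity(list(thetas), list(ses))
                rows.append({"outcome": out_name, "stratum": "men_vs_women",
                             "exposure": exp_name, "method": "subgroup_heterogeneity",
                             "q_a": q, "q_a_df": df, "q_a_pvalue": p, "error": None})
    return _provenance(pd.DataFrame(rows), config)


def run_power_report(config: AnalysisConfig) -> pd.DataFrame:
    """A-priori power over an OR grid for every configured analysis cell."""
    if not config.power_cells or not config.r_squared:
        raise ValueError("power report needs power_cells and r_squared in the config")
    specs = {}
    for exp_name, r2 in config.r_squared.items():
        for cell, counts in config.power_cells.items():
            specs[f"{exp_name}/{cell}"] = (counts["n_cases"], counts["n_controls"], r2)
    return _provenance(power_grid(specs, alpha=config.alpha), config)


def forest_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready forest rows (label, or_, ci_low, ci_high, group) on OR scale."""
    rows = results.dropna(subset=["beta"]) if "beta" in results else results
    return pd.DataFrame({
        "label": rows["exposure"].astype(str) + " → " + rows["outcome"].astype(str)
                 + " (" + rows["stratum"].astype(str) + ", " + rows["method"].astype(str) + ")",
        "or_": np.exp(rows["beta"].astype(float)),
        "ci_low": np.exp(rows["ci_low"].astype(float)),
        "ci_high": np.exp(rows["ci_high"].astype(float)),
        "group": rows["stratum"],
    })
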