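"""Instrument-strength diagnostics for univariable MR.

Strength of a genetic instrument is summarised by the F-statistic
F = R² (N − 2) / (1 − R²), where R² is the fraction of exposure variance the
instrument explains and N the discovery-GWAS sample size.  F below 10 is the
conventional flag for weak-instrument bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sumstats import InstrumentSet

WEAK_F_THRESHOLD = 10.0


@dataclass
class StrengthReport:
    per_snp_f: list[tuple[str, float]]
    min_f: float
    r_squared_total: float
    n_gwas: float
    weak_instruments: bool  # True when min_f < 10


def f_statistic(r_squared: float, n: float) -> float:
    """F = R²(N−2)/(1−R²) for an instrument explaining R² in a GWAS of N."""
    if not 0.0 <= r_squared < 1.0:
        raise ValueError(f"r_squared must lie in [0, 1), got {r_squared}")
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    return r_squared * (n - 2.0) / (1.0 - r_squared)


def approx_r_squared(eaf: float, beta: float, var_trait: float = 1.0) -> float:
    """Per-SNP variance explained, 2p(1−p)β²/Var(trait).

    The standard approximation when the source GWAS reports no per-SNP R²;
    assumes Hardy–Weinberg genotype variance 2p(1−p).
    """
    return 2.0 * eaf * (1.0 - eaf) * beta * beta / var_trait


def strength_report(
    instrument_set: InstrumentSet,
    per_snp_r2: list[float] | None = None,
    var_trait: float = 1.0,
) -> StrengthReport:
    """Per-SNP and minimum F for an instrument set.

    When ``per_snp_r2`` is not supplied, each SNP's R² is approximated from
    its allele frequency and beta (requires eaf on every record).
    """
    n = instrument_set.n_gwas
    if n is None:
        raise ValueError("instrument set must carry n_gwas for F-statistics")
    if per_snp_r2 is None:
        missing = [a.rsid for a in instrument_set if a.eaf is None]
        if missing:
            raise ValueError(f"eaf needed to approximate per-SNP r²; missing for {missing[:5]}")
        per_snp_r2 = [approx_r_squared(a.eaf, a.beta, var_trait) for a in instrument_set]
    if len(per_snp_r2) != len(instrument_set):
        raise ValueError(
            f"need one r² per SNP: {len(per_snp_r2)} r² values for "
            f"{len(instrument_set)} SNPs")
    per_snp_f = [(a.rsid, f_statistic(r2, n))
                 for a, r2 in zip(instrument_set, per_snp_r2)]
    min_f = min(f for _, f in per_snp_f)
    total = float(np.sum(per_snp_r2))
    return StrengthReport(
        per_snp_f=per_snp_f,
        min_f=min_f,
        r_squared_total=total,
        n_gwas=n,
        weak_instruments=min_f < WEAK_F_THRESHOLD,
    )
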