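"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR requires every beta at a SNP to refer to the same effect
allele.  Records are aligned to the first exposure's effect allele: where a
second table reports the swapped allele pair, its beta sign is flipped (and
its effect-allele frequency complemented); irreconcilable allele pairs are
dropped and logged with a reason code.  All tables are assumed coded on the
forward strand, so palindromic (A/T, C/G) SNPs are by default treated like
any other; an optional strict mode drops palindromic SNPs whose allele
frequency is too close to 0.5 for the strand to be checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import InstrumentSet, SnpAssociation, SumstatsError

logger = logging.getLogger(__name__)


class HarmonizationError(ValueError):
    """Raised when harmonization cannot produce a usable SNP set."""


@dataclass(frozen=True)
class HarmonizedRecord:
    """SNP-aligned betas: exposure(s) gamma and outcome Gamma on one allele."""

    rsid: str
    gamma1: float
    se_g1: float
    Gamma: float
    se_G: float
    gamma2: float | None = None
    se_g2: float | None = None

    def __post_init__(self) -> None:
        if self.se_g1 <= 0 or self.se_G <= 0:
            raise HarmonizationError(f"{self.rsid}: standard errors must be > 0")
        if (self.gamma2 is None) != (self.se_g2 is None):
            raise HarmonizationError(f"{self.rsid}: gamma2 and se_g2 must come together")
        if self.se_g2 is not None and self.se_g2 <= 0:
            raise HarmonizationError(f"{self.rsid}: standard errors must be > 0")


@dataclass
class HarmonizedSet:
    """Estimator-ready aligned records for one or two exposures."""

    records: list[HarmonizedRecord]
    n_exposures: int = 1

    def __post_init__(self) -> None:
        if self.n_exposures not in (1, 2):
            raise HarmonizationError("n_exposures must be 1 or 2")
        if not self.records:
            raise HarmonizationError("HarmonizedSet must contain at least one record")
        rsids = [r.rsid for r in self.records]
        if len(set(rsids)) != len(rsids):
            raise HarmonizationError("duplicate rsid in HarmonizedSet")
        if self.n_exposures == 2 and any(r.gamma2 is None for r in self.records):
            raise HarmonizationError("two-exposure set has records without gamma2")

    @property
    def L(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def arrays(self) -> dict[str, np.ndarray]:
        """Column vectors as float arrays (gamma2/se_g2 only when present)."""
        out = {
            "gamma1": np.array([r.gamma1 for r in self.records], dtype=float),
            "se_g1": np.array([r.se_g1 for r in self.records], dtype=float),
            "Gamma": np.array([r.Gamma for r in self.records], dtype=float),
            "se_G": np.array([r.se_G for r in self.records], dtype=float),
        }
        if self.n_exposures == 2:
            out["gamma2"] = np.array([r.gamma2 for r in self.records], dtype=float)
            out["se_g2"] = np.array([r.se_g2 for r in self.records], dtype=float)
        return out


@dataclass(frozen=True)
class DroppedSnp:
    rsid: str
    reason: str  # "allele_mismatch" | "palindromic_ambiguous"
    detail: str = ""


def _align(base: SnpAssociation, other: SnpAssociation) -> tuple[float, float] | None:
    """Return (beta, se) of `other` re-coded onto `base`'s effect allele.

    None when the allele pairs cannot be reconciled (forward strand assumed,
    so no strand-complement rescue is attempted).
    """
    if (other.effect_allele, other.other_allele) == (base.effect_allele, base.other_allele):
        return other.beta, other.se
    if (other.effect_allele, other.other_allele) == (base.other_allele, base.effect_allele):
        return -other.beta, other.se
    return None


def harmonize(
    exposures: InstrumentSet | list[InstrumentSet],
    outcome: InstrumentSet,
    strict_palindromes: bool = False,
    ambiguous_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align one or two exposure tables with an outcome table by rsid.

    SNPs present in every supplied table are retained, in the first
    exposure's order.  Swapped allele pairs flip the beta sign;
    irreconcilable pairs are dropped and logged.  With
    ``strict_palindromes=True``, palindromic SNPs whose exposure eaf falls
    inside ``ambiguous_eaf_window`` are dropped as strand-ambiguous.
    """
    if isinstance(exposures, InstrumentSet):
        exposures = [exposures]
    if not 1 <= len(exposures) <= 2:
        raise HarmonizationError("harmonize takes one or two exposure tables")

    exp1 = exposures[0]
    exp2 = exposures[1] if len(exposures) == 2 else None
    out_by_rsid = outcome.by_rsid()
    exp2_by_rsid = exp2.by_rsid() if exp2 is not None else None

    records: list[HarmonizedRecord] = []
    dropped: list[DroppedSnp] = []
    for base in exp1:
        if base.rsid not in out_by_rsid:
            continue
        if exp2_by_rsid is not None and base.rsid not in exp2_by_rsid:
            continue
        if strict_palindromes and base.is_palindromic:
            lo, hi = ambiguous_eaf_window
            if base.eaf is None or lo < base.eaf < hi:
                dropped.append(DroppedSnp(base.rsid, "palindromic_ambiguous",
                                          f"eaf={base.eaf}"))
                continue
        aligned_out = _align(base, out_by_rsid[base.rsid])
        if aligned_out is None:
            dropped.append(DroppedSnp(
                base.rsid, "allele_mismatch",
                f"exposure {base.effect_allele}/{base.other_allele} vs outcome "
                f"{out_by_rsid[base.rsid].effect_allele}/{out_by_rsid[base.rsid].other_allele}"))
            continue
        gamma2 = se_g2 = None
        if exp2_by_rsid is not None:
            aligned_exp2 = _align(base, exp2_by_rsid[base.rsid])
            if aligned_exp2 is None:
                dropped.append(DroppedSnp(
                    base.rsid, "allele_mismatch",
                    f"exposure 1 {base.effect_allele}/{base.other_allele} vs exposure 2 "
                    f"{exp2_by_rsid[base.rsid].effect_allele}/{exp2_by_rsid[base.rsid].other_allele}"))
                continue
            gamma2, se_g2 = aligned_exp2
        records.append(HarmonizedRecord(
            rsid=base.rsid, gamma1=base.beta, se_g1=base.se,
            Gamma=aligned_out[0], se_G=aligned_out[1],
            gamma2=gamma2, se_g2=se_g2))

    for d in dropped:
        logger.info("harmonize: dropped %s (%s) %s", d.rsid, d.reason, d.detail)
    if not records:
        raise HarmonizationError(
            "no SNP survives harmonization (empty intersection or all dropped)")
    hset = HarmonizedSet(records=records, n_exposures=1 if exp2 is None else 2)
    hset.dropped = dropped  # type: ignore[attr-defined]  # audit trail
    return hset


# ---------------------------------------------------------------------------
# Instrument union and greedy LD clumping (for multivariable instruments)
# ---------------------------------------------------------------------------

def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square r² matrix from TSV with rsid header row and column."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    return mat


def _check_ld(ld: pd.DataFrame, rsids: list[str]) -> None:
    missing = [r for r in rsids if r not in ld.index or r not in ld.columns]
    if missing:
        raise HarmonizationError(f"LD matrix does not cover SNPs: {missing}")
    sub = ld.loc[rsids, rsids].to_numpy(dtype=float)
    if not np.allclose(sub, sub.T, atol=1e-8):
        raise HarmonizationError("LD matrix is not symmetric")
    if not np.allclose(np.diag(sub), 1.0, atol=1e-8):
        raise HarmonizationError("LD matrix diagonal must be 1")


def union_instrument_set(
    set1: InstrumentSet,
    set2: InstrumentSet,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
) -> list[str]:
    """Union of two instrument SNP lists with optional greedy LD clumping.

    With an LD matrix, SNPs are visited in ascending order of their best
    exposure p-value and retained only if their r² with every
    already-retained SNP is <= ``r2_threshold`` — the standard greedy clump.
    """
    best_p: dict[str, float] = {}
    order: list[str] = []
    for iset in (set1, set2):
        for a in iset:
            p = a.pvalue if a.pvalue is not None else 1.0
            if a.rsid not in best_p:
                order.append(a.rsid)
            best_p[a.rsid] = min(best_p.get(a.rsid, 1.0), p)
    if ld is None:
        return order

    _check_ld(ld, order)
    # stable sort: ties broken by first-seen order
    ranked = sorted(order, key=lambda r: (best_p[r], order.index(r)))
    kept: list[str] = []
    for rsid in ranked:
        if all(float(ld.loc[rsid, k]) <= r2_threshold for k in kept):
            kept.append(rsid)
    return [r for r in order if r in set(kept)]
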