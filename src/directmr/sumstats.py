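"""Reading, validating and writing GWAS summary-statistics tables.

The atom of every analysis is one SNP's allele-coded association estimate
(:class:`SnpAssociation`); an instrument is a collection of those for one
exposure and stratum (:class:`InstrumentSet`).  Canonical on-disk format is a
headered TSV; a ``column_map`` translates foreign dialects ("EA",
"Effect_allele", ...) onto the canonical column names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: canonical association-table columns, in on-disk order
ASSOC_COLUMNS = ("rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n")

#: canonical result-table columns, in on-disk order
RESULT_COLUMNS = (
    "exposure", "outcome", "stratum", "method", "n_snp", "beta", "se",
    "or_", "ci_low", "ci_high", "pvalue", "q_stat", "q_df", "q_pvalue",
    "egger_intercept", "egger_intercept_se", "egger_intercept_pvalue",
)


class SumstatsError(ValueError):
    """Raised for malformed or invalid summary-statistics input."""


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's effect estimate, coded on an explicit effect allele.

    ``beta`` is the additive effect per copy of ``effect_allele`` — in
    per-category units for a body-size exposure, in log-odds for a
    case-control outcome.  ``eaf``, ``pvalue`` and ``n`` are optional.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def validate(self) -> None:
        if not self.rsid:
            raise SumstatsError("rsid must be non-empty")
        for name, allele in (("effect_allele", self.effect_allele),
                             ("other_allele", self.other_allele)):
            if allele not in VALID_ALLELES:
                raise SumstatsError(
                    f"{name} {allele!r} is not a single-base allele (A/C/G/T)")
        if self.effect_allele == self.other_allele:
            raise SumstatsError("effect_allele and other_allele are identical")
        if not math.isfinite(self.beta):
            raise SumstatsError("beta must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise SumstatsError(f"se must be strictly positive, got {self.se}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise SumstatsError(f"eaf must lie in (0, 1), got {self.eaf}")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise SumstatsError(f"pvalue must lie in [0, 1], got {self.pvalue}")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class InstrumentSet:
    """A validated set of instrument SNPs for one exposure and stratum."""

    exposure_name: str
    associations: list[SnpAssociation]
    stratum: str = "overall"
    r_squared: float | None = None
    n_gwas: float | None = None

    def __post_init__(self) -> None:
        if not self.associations:
            raise SumstatsError("InstrumentSet needs at least one association")
        if self.r_squared is not None and not (0.0 <= self.r_squared < 1.0):
            raise SumstatsError(f"r_squared must lie in [0, 1), got {self.r_squared}")
        seen: set[str] = set()
        for assoc in self.associations:
            if assoc.rsid in seen:
                raise SumstatsError(f"duplicate rsid {assoc.rsid!r}")
            seen.add(assoc.rsid)

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self):
        return iter(self.associations)

    @property
    def rsids(self) -> list[str]:
        return [a.rsid for a in self.associations]

    def by_rsid(self) -> dict[str, SnpAssociation]:
        return {a.rsid: a for a in self.associations}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rsid": a.rsid, "effect_allele": a.effect_allele,
                "other_allele": a.other_allele, "eaf": a.eaf, "beta": a.beta,
                "se": a.se, "pvalue": a.pvalue, "n": a.n,
            }
            for a in self.associations
        ]
        return pd.DataFrame(rows, columns=list(ASSOC_COLUMNS))


def _parse_optional(value, row_no: int, column: str) -> float | None:
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in {"na", "nan", "none"}:
        return None
    try:
        return float(text)
    except ValueError:
        raise SumstatsError(f"row {row_no}: column {column!r} is not numeric: {value!r}")


def _parse_required(value, row_no: int, column: str) -> float:
    parsed = _parse_optional(value, row_no, column)
    if parsed is None:
        raise SumstatsError(f"row {row_no}: column {column!r} is required but empty")
    return parsed


def read_associations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    exposure_name: str = "",
    stratum: str = "overall",
    r_squared: float | None = None,
    n_gwas: float | None = None,
) -> InstrumentSet:
    """Read a headered TSV of SNP associations into a validated InstrumentSet.

    ``column_map`` maps canonical names onto the file's column names, e.g.
    ``{"effect_allele": "EA"}``.  Rows violating an invariant are rejected
    with a message naming the 1-based data-row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    mapped = {canon: column_map.get(canon, canon) for canon in ASSOC_COLUMNS}
    for canon in ("rsid", "effect_allele", "other_allele", "beta", "se"):
        if mapped[canon] not in table.columns:
            raise SumstatsError(
                f"{path.name}: required column {mapped[canon]!r} "
                f"(for {canon!r}) missing from header {list(table.columns)}")

    associations: list[SnpAssociation] = []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        record = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        get = lambda canon: record.get(mapped[canon])  # noqa: E731
        try:
            assoc = SnpAssociation(
                rsid=str(get("rsid")).strip(),
                effect_allele=str(get("effect_allele")).strip().upper(),
                other_allele=str(get("other_allele")).strip().upper(),
                beta=_parse_required(get("beta"), i, "beta"),
                se=_parse_required(get("se"), i, "se"),
                eaf=_parse_optional(get("eaf"), i, "eaf") if mapped["eaf"] in table.columns else None,
                pvalue=_parse_optional(get("pvalue"), i, "pvalue") if mapped["pvalue"] in table.columns else None,
                n=_parse_optional(get("n"), i, "n") if mapped["n"] in table.columns else None,
            )
            assoc.validate()
        except SumstatsError as exc:
            raise SumstatsError(f"{path.name}: row {i}: {exc}") from exc
        associations.append(assoc)

    try:
        return InstrumentSet(
            exposure_name=exposure_name or path.stem,
            stratum=stratum,
            associations=associations,
            r_squared=r_squared,
            n_gwas=n_gwas,
        )
    except SumstatsError as exc:
        raise SumstatsError(f"{path.name}: {exc}") from exc


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def write_associations(instrument_set: InstrumentSet, path: str | Path) -> None:
    """Write an InstrumentSet to the canonical TSV schema (10 sig. digits)."""
    path = Path(path)
    lines = ["\t".join(ASSOC_COLUMNS)]
    for a in instrument_set:
        lines.append("\t".join(_fmt(v) for v in (
            a.rsid, a.effect_allele, a.other_allele, a.eaf, a.beta, a.se, a.pvalue, a.n)))
    path.write_text("\n".join(lines) + "\n")


def write_results_table(estimates: Sequence, path: str | Path) -> None:
    """Write MR estimates, one row each, in the canonical result layout.

    Accepts any objects exposing the result fields (MrEstimate does);
    values round-trip losslessly at 10 significant digits.
    """
    if not estimates:
        raise SumstatsError("refusing to write an empty results table")
    path = Path(path)
    lines = ["\t".join(RESULT_COLUMNS)]
    for est in estimates:
        lines.append("\t".join(_fmt(getattr(est, col, None)) for col in RESULT_COLUMNS))
    path.write_text("\n".join(lines) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (empty cells become NaN)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise SumstatsError(f"results table missing columns: {missing}")
    return table
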