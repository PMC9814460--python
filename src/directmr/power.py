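"""Analytic a priori power for binary-outcome two-sample MR.

Uses the standard two-stage normal approximation: with total outcome sample
N, case fraction K, instrument variance explained R² and per-category odds
ratio OR, the expected Wald statistic is
z = |ln OR| · sqrt(N · R² · K(1−K)) and two-sided power at level alpha is
Phi(z − z_{1−alpha/2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class PowerSpec:
    n_cases: int
    n_controls: int
    r_squared: float
    odds_ratio: float
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not 0.0 < self.r_squared < 1.0:
            raise ValueError(f"r_squared must lie in (0, 1), got {self.r_squared}")
        if self.odds_ratio <= 0:
            raise ValueError(f"odds_ratio must be positive, got {self.odds_ratio}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


def mr_power_binary(spec: PowerSpec) -> float:
    """Two-sided power to detect ``spec.odds_ratio`` with an MR instrument."""
    spec.validate()
    n = spec.n_cases + spec.n_controls
    k = spec.n_cases / n
    z = abs(math.log(spec.odds_ratio)) * math.sqrt(n * spec.r_squared * k * (1.0 - k))
    return float(stats.norm.cdf(z - stats.norm.ppf(1.0 - spec.alpha / 2.0)))


def min_detectable_or(
    n_cases: int,
    n_controls: int,
    r_squared: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    tol: float = 1e-6,
) -> float:
    """Smallest OR > 1 reaching ``target_power``, by bisection to ``tol``."""
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")

    def power_at(or_: float) -> float:
        return mr_power_binary(PowerSpec(n_cases, n_controls, r_squared, or_, alpha))

    lo, hi = 1.0 + 1e-12, 2.0
    while power_at(hi) < target_power:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("no attainable OR below 1e6 reaches the target power")
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def power_grid(
    specs: "dict[str, tuple[int, int, float]]",
    or_grid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power table over an OR grid for labelled (n_cases, n_controls, r²) cells.

    ``specs`` maps a cell label (e.g. "early_life/colorectal/overall") to its
    sample counts and instrument R²; the default OR grid is 1.05–1.50 in
    steps of 0.05.
    """
    if or_grid is None:
        or_grid = np.arange(1.05, 1.501, 0.05)
    rows = []
    for label, (n_cases, n_controls, r2) in specs.items():
        for or_ in or_grid:
            p = mr_power_binary(PowerSpec(n_cases, n_controls, r2, float(or_), alpha))
            rows.append({"cell": label, "n_cases": n_cases, "n_controls": n_controls,
                         "r_squared": r2, "odds_ratio": round(float(or_), 6),
                         "power": p})
    return pd.DataFrame(rows)
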