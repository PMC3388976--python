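"""Dyar's-rule analysis of instar head-width progressions.

Dyar's rule: across moults the sclerotized head capsule grows in
geometric progression, i.e. the ratio of mean head widths of
consecutive instars is roughly constant, typically between 1.1 and 1.9
and usually near 1.4.  An instar hypothesis is therefore tested by (a)
checking every per-moult ratio against that band and (b) regressing
ln(mean head width) on instar index and requiring a near-perfect linear
fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention of the published tables)."""
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(exp, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DyarFit:
    """Growth-ratio statistics and log-linear regression of a mean sequence.

    ``mean_rate`` is the arithmetic mean of the per-moult ratios;
    ``implied_rate`` = exp(slope) of the OLS fit of ln μ_i on i is the
    regression's view of the same constant and is reported alongside.
    """

    rates: tuple[float, ...]
    mean_rate: float
    slope: float
    intercept: float
    implied_rate: float
    r_squared: Optional[float]

    @property
    def k(self) -> int:
        return len(self.rates) + 1

    def to_dict(self) -> dict:
        return {
            "rates": list(self.rates),
            "mean_rate": self.mean_rate,
            "slope": self.slope,
            "intercept": self.intercept,
            "implied_rate": self.implied_rate,
            "r_squared": self.r_squared,
        }


@dataclass(frozen=True)
class DyarCheck:
    name: str
    passed: bool
    detail: str

    def to_dict(self) -> dict:
        return {"name": self.name, "passed": self.passed, "detail": self.detail}


@dataclass(frozen=True)
class DyarVerdict:
    """Pass/fail verdict with one entry per individual check."""

    passed: bool
    checks: tuple[DyarCheck, ...]

    def failed_checks(self) -> list[DyarCheck]:
        return [c for c in self.checks if not c.passed]

    def to_dict(self) -> dict:
        return {"passed": self.passed, "checks": [c.to_dict() for c in self.checks]}


def _check_means(means) -> np.ndarray:
    m = np.asarray(means, dtype=float).ravel()
    if np.any(m <= 0):
        raise ValidationError("means must be positive")
    if np.any(np.diff(m) <= 0):
        raise ValidationError(f"means must be strictly increasing, got {m.tolist()}")
    return m


def growth_rates(means) -> np.ndarray:
    """Per-moult ratios r_i = μ_{i+1} / μ_i of an increasing mean sequence."""
    m = _check_means(means)
    if m.size < 2:
        raise ValidationError(f"need >= 2 means for growth rates, got {m.size}")
    return m[1:] / m[:-1]


def dyar_regression(means) -> DyarFit:
    """OLS of ln μ_i on instar index i = 1..K, with per-moult ratios.

    R² is the regression sum of squares over the total sum of squares
    of ln μ.  Requires K >= 3 (R² on two points is vacuously 1).
    """
    m = _check_means(means)
    if m.size < 3:
        raise InsufficientDataError(
            f"Dyar regression needs >= 3 means, got {m.size}"
        )
    idx = np.arange(1, m.size + 1, dtype=float)
    res = stats.linregress(idx, np.log(m))
    rates = growth_rates(m)
    return DyarFit(
        rates=tuple(float(r) for r in rates),
        mean_rate=float(np.mean(rates)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        implied_rate=float(math.exp(res.slope)),
        r_squared=float(res.rvalue**2),
    )


def validate_dyar(
    fit: DyarFit,
    lo: float = 1.1,
    hi: float = 1.9,
    min_r2: float = 0.9,
) -> DyarVerdict:
    """Check a fitted progression against the Dyar band and fit quality.

    Passes iff every per-moult ratio lies in [lo, hi] and R² >= min_r2.
    """
    checks = []
    for i, r in enumerate(fit.rates, start=1):
        ok = lo <= r <= hi
        checks.append(
            DyarCheck(
                name=f"rate_{i}_{i + 1}_in_band",
                passed=ok,
                detail=f"r_{i}={r:.4f} {'in' if ok else 'outside'} [{lo}, {hi}]",
            )
        )
    if fit.r_squared is not None:
        ok = fit.r_squared >= min_r2
        checks.append(
            DyarCheck(
                name="r_squared_min",
                passed=ok,
                detail=f"R²={fit.r_squared:.4f} {'>=':s} {min_r2}" if ok else f"R²={fit.r_squared:.4f} < {min_r2}",
            )
        )
    return DyarVerdict(passed=all(c.passed for c in checks), checks=tuple(checks))
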