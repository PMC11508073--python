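"""Absorbed-dose estimation by LQ curve inversion with exact Poisson limits.

The point estimate inverts the calibration curve at the observed yield
y = X/N: the positive root of beta*D^2 + alpha*D + (c - y) = 0.  The 95%
confidence interval propagates exact (Garwood) Poisson limits on the raw
count X through the same inversion:

    X_lower = chi2.ppf(alpha/2, 2X) / 2        (0 when X = 0)
    X_upper = chi2.ppf(1 - alpha/2, 2X + 2) / 2

so LCL = D(X_lower/N) and UCL = D(X_upper/N).  Calibration-curve
uncertainty is not folded in by default; ``method="delta"`` instead
reports a symmetric interval from the delta-method SE of the dose,
sqrt(s_y^2)/(dY/dD), which does not reproduce exact-limit intervals and is
offered as an explicitly labelled alternative.

Also provides the triage scoring-truncation rule: stop after 50 cells or
30 cumulative dicentric equivalents, whichever comes first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .lq_calibration import CalibrationCurve
from .score_data import CellRecord, ScoreSheetError

__all__ = [
    "PoissonLimits",
    "DoseEstimate",
    "invert_curve",
    "exact_poisson_limits",
    "estimate_dose",
    "triage_truncate",
]


@dataclass(frozen=True)
class PoissonLimits:
    """Exact two-sided confidence limits for a Poisson count."""

    x: int
    lower: float
    upper: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        assert 0.0 <= self.lower <= self.x <= self.upper


@dataclass(frozen=True)
class DoseEstimate:
    """Point dose with confidence limits and the inputs that produced it."""

    dose_gy: float
    lcl_gy: float
    ucl_gy: float
    confidence: float
    x: int
    n_cells: int
    method: str  # "exact_poisson" | "delta"
    curve_source: str = ""
    se_gy: float | None = None  # delta-method SE, populated for method="delta"


def invert_curve(curve: CalibrationCurve, yield_per_cell: float) -> float:
    """Dose (Gy) at which the curve predicts the given yield per cell.

    Yields at or below the background c map to 0 Gy.
    """
    y = float(yield_per_cell)
    if y < 0:
        raise ValueError(f"yield must be >= 0, got {y}")
    c, a, b = curve.c, curve.alpha, curve.beta
    if b < 0:
        raise ScoreSheetError(f"unsupported curve: beta must be >= 0, got {b}")
    if y <= c:
        return 0.0
    if b == 0.0:
        if a <= 0.0:
            raise ScoreSheetError("curve is not invertible: alpha = beta = 0")
        return (y - c) / a
    return (-a + math.sqrt(a * a + 4.0 * b * (y - c))) / (2.0 * b)


def exact_poisson_limits(x: int, confidence: float = 0.95) -> PoissonLimits:
    """Garwood exact confidence limits for a Poisson count, from chi-square
    quantiles: lower = chi2.ppf(a/2, 2X)/2 (0 for X=0),
    upper = chi2.ppf(1-a/2, 2X+2)/2, a = 1 - confidence."""
    if not isinstance(x, (int,)) or isinstance(x, bool):
        if not (isinstance(x, float) and x.is_integer()):
            raise ScoreSheetError(f"count must be a non-negative integer, got {x!r}")
        x = int(x)
    if x < 0:
        raise ScoreSheetError(f"count must be >= 0, got {x}")
    if not 0.0 < confidence < 1.0:
        raise ScoreSheetError(f"confidence must be in (0, 1), got {confidence}")
    a = 1.0 - confidence
    lower = 0.0 if x == 0 else float(stats.chi2.ppf(a / 2.0, 2 * x) / 2.0)
    upper = float(stats.chi2.ppf(1.0 - a / 2.0, 2 * x + 2) / 2.0)
    return PoissonLimits(x=x, lower=lower, upper=upper, confidence=confidence)


def estimate_dose(
    curve: CalibrationCurve,
    x: int,
    n_cells: int,
    confidence: float = 0.95,
    method: str = "exact_poisson",
) -> DoseEstimate:
    """Absorbed dose from X aberrations in N cells via curve inversion.

    ``exact_poisson`` (default) propagates Garwood count limits through the
    inverse curve; ``delta`` reports dose_hat +/- z * se where se is the
    yield SE sqrt(y/N) divided by the curve slope at dose_hat.
    """
    if n_cells < 1:
        raise ScoreSheetError(f"need >= 1 scored cell, got {n_cells}")
    y = x / n_cells
    dose = invert_curve(curve, y)
    if method == "exact_poisson":
        lim = exact_poisson_limits(x, confidence)
        lcl = invert_curve(curve, lim.lower / n_cells)
        ucl = invert_curve(curve, lim.upper / n_cells)
        se = None
    elif method == "delta":
        # Poisson yield SE propagated through the inverse slope; no exact
        # coverage guarantee, labelled for what it is.
        se_y = math.sqrt(max(y, 1.0 / n_cells) / n_cells)
        slope = curve.alpha + 2.0 * curve.beta * dose
        se = se_y / slope if slope > 0 else float("inf")
        z = stats.norm.ppf(0.5 + confidence / 2.0)
        lcl = max(0.0, dose - z * se)
        ucl = dose + z * se
    else:
        raise ScoreSheetError(f"unknown CI method {method!r}")
    return DoseEstimate(
        dose_gy=dose,
        lcl_gy=lcl,
        ucl_gy=ucl,
        confidence=confidence,
        x=int(x),
        n_cells=int(n_cells),
        method=method,
        curve_source=curve.source,
        se_gy=se,
    )


def triage_truncate(
    cells: Sequence[CellRecord], max_cells: int = 50, max_dicentrics: int = 30
) -> list[CellRecord]:
    """Triage-mode scoring truncation: the shortest prefix of the scored
    cell sequence that reaches either ``max_cells`` cells or a cumulative
    ``max_dicentrics`` dicentric equivalents."""
    out: list[CellRecord] = []
    cum = 0
    for cell in cells:
        if len(out) >= max_cells:
            break
        out.append(cell)
        cum += cell.dicentric_equivalents
        if cum >= max_dicentrics:
            break
    return out
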