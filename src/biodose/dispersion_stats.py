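"""Per-dose summary statistics for aberration counts.

For a dose point with N scored cells and class total X, the summary reports
the mean yield Y = X/N with its empirical standard error, the sample
variance s^2 (N-1 denominator), the variance-to-mean dispersion index
sigma^2/y-bar with its standard error, and the Papworth U statistic

    U = (s^2/Y - 1) / sqrt(2 (1 - 1/X) / (N - 1)),

which is approximately standard normal when per-cell counts are Poisson.
U > 0 indicates overdispersion (e.g. partial-body or high-LET exposure),
U < 0 underdispersion.  U and the dispersion index are undefined for
Y = 0 or X < 2 and reported as ``None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .score_data import (
    DistributionUnavailableError,
    DosePoint,
    ScoreSheet,
    ScoreSheetError,
    resolve_class,
)

__all__ = ["DosePointSummary", "summarize_distribution", "summarize_dose_point", "summarize_sheet"]


@dataclass(frozen=True)
class DosePointSummary:
    """Yield, dispersion and U test for one dose point and aberration class."""

    dose_gy: float
    n_cells: int
    total: int
    yield_per_cell: float
    se_yield: float | None
    sample_variance: float | None
    dispersion_index: float | None
    se_dispersion: float | None
    u_statistic: float | None
    aberration_class: str = "dicentric_equivalents"
    note: str | None = None

    def round2(self) -> dict[str, float | None]:
        """Two-decimal view matching how published tables print these columns.

        For display/comparison only; all internal arithmetic keeps full
        precision.
        """
        r = lambda v: None if v is None else round(v, 2)
        return {
            "yield": r(self.yield_per_cell),
            "se_yield": r(self.se_yield),
            "var_mean": r(self.dispersion_index),
            "se_var_mean": r(self.se_dispersion),
            "u": r(self.u_statistic),
        }


def summarize_distribution(
    distribution: dict[int, int],
    *,
    dose_gy: float = 0.0,
    aberration_class: str = "dicentric_equivalents",
) -> DosePointSummary:
    """Compute the summary from a count -> cells mapping."""
    n = sum(distribution.values())
    if n < 2:
        raise ScoreSheetError(f"dispersion statistics need N >= 2 cells, got {n}")
    x = sum(k * m for k, m in distribution.items())
    sum_k2 = sum(k * k * m for k, m in distribution.items())
    y = x / n
    s2 = (sum_k2 - x * x / n) / (n - 1)
    se_y = math.sqrt(s2 / n)
    if x >= 2 and y > 0:
        vm = s2 / y
        se_vm = math.sqrt(2.0 * (1.0 - 1.0 / x) / (n - 1))
        u = (vm - 1.0) / se_vm
    else:
        vm = se_vm = u = None
    return DosePointSummary(
        dose_gy=dose_gy,
        n_cells=n,
        total=x,
        yield_per_cell=y,
        se_yield=se_y,
        sample_variance=s2,
        dispersion_index=vm,
        se_dispersion=se_vm,
        u_statistic=u,
        aberration_class=resolve_class(aberration_class),
    )


def summarize_dose_point(
    point: DosePoint, aberration_class: str = "dicentric_equivalents"
) -> DosePointSummary:
    """Summarize one dose point; requires a per-cell distribution."""
    cls = resolve_class(aberration_class)
    dist = point.distribution(cls)  # raises DistributionUnavailableError if absent
    summary = summarize_distribution(dist, dose_gy=point.dose_gy, aberration_class=cls)
    return summary


def summarize_sheet(
    sheet: ScoreSheet, aberration_class: str = "dicentric_equivalents"
) -> list[DosePointSummary]:
    """One summary per dose point, in ascending dose order.

    Dose points recorded as totals only (no distribution) still contribute
    a summary with the yield; the variance-based statistics are ``None``
    and the problem is noted rather than aborting the whole sheet.
    """
    cls = resolve_class(aberration_class)
    out: list[DosePointSummary] = []
    for point in sorted(sheet.points, key=lambda p: p.dose_gy):
        try:
            out.append(summarize_dose_point(point, cls))
        except DistributionUnavailableError as exc:
            x = point.total(cls)
            n = point.n_cells
            out.append(
                DosePointSummary(
                    dose_gy=point.dose_gy,
                    n_cells=n,
                    total=x,
                    yield_per_cell=x / n,
                    se_yield=None,
                    sample_variance=None,
                    dispersion_index=None,
                    se_dispersion=None,
                    u_statistic=None,
                    aberration_class=cls,
                    note=str(exc),
                )
            )
    return out
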