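"""Regenerate the published summary statistics and dose estimates from the
packaged fixtures and compare them with the printed values.

Blocks of the report:

* ``dispersion_table`` — Yield, Var/Mean and U per dose recomputed from the
  dicentric count distributions, against the printed columns (tolerance
  0.02, the printing precision);
* ``yields`` — exact-arithmetic yield checks (dicentrics at 0.1 and 20 Gy,
  combined dicentrics+rings at 20 Gy, fixation-time yields);
* ``dose_estimates`` — Garwood-limit dose estimates from the fixation-time
  counts through the FISH calibration curve, against the printed point
  estimates and confidence limits for the nine irradiated cells
  (tolerance 0.02 Gy);
* ``correlations`` — Pearson r between metaphase and G2-PCC total-aberration
  yields per donor (expected >= 0.99);
* ``ratios`` — donor-2/donor-1 G2-PCC ring-yield ratio at 5 Gy and the
  fragment/dicentric ratio at 7.5 Gy, donor 1 metaphases (expected >= 1.6).
"""

from __future__ import annotations

from . import fixtures
from .dispersion_stats import summarize_sheet
from .dose_estimation import estimate_dose
from .spectrum_comparison import yield_correlation

__all__ = ["reproduce_paper", "format_report"]

TOL = 0.02  # two-decimal printing tolerance

_FRAGMENTS = ("compound_fragments", "terminal_fragments", "interstitial_fragments")


def _check(name: str, computed: float, expected: float, tol: float = TOL) -> dict:
    computed, expected = float(computed), float(expected)
    return {
        "name": name,
        "computed": computed,
        "expected": expected,
        "tolerance": tol,
        "pass": bool(abs(computed - expected) <= tol),
    }


def _check_ge(name: str, computed: float, bound: float) -> dict:
    computed = float(computed)
    return {
        "name": name,
        "computed": computed,
        "expected": f">= {bound}",
        "tolerance": 0.0,
        "pass": bool(computed >= bound),
    }


def reproduce_paper() -> dict:
    """Run every fixture-based reproduction check and return the report."""
    report: dict = {"tolerance_gy": TOL, "blocks": {}}

    # -- dispersion statistics table -------------------------------------
    sheet = fixtures.g2pcc_dicentric_sheet()
    printed = fixtures.g2pcc_dicentric_printed_stats()
    summaries = {s.dose_gy: s for s in summarize_sheet(sheet)}
    rows = []
    for rec in printed.to_dict("records"):
        s = summaries[float(rec["dose_gy"])]
        rows.append(_check(f"{rec['dose_gy']} Gy yield", s.yield_per_cell, rec["yield"]))
        rows.append(_check(f"{rec['dose_gy']} Gy var/mean", s.dispersion_index, rec["var_mean"]))
        rows.append(_check(f"{rec['dose_gy']} Gy U", s.u_statistic, rec["u"]))
    report["blocks"]["dispersion_table"] = rows

    # -- exact yield arithmetic ------------------------------------------
    rings = fixtures.g2pcc_ring_sheet()
    dic_01 = sheet.point_at(0.1)
    dic_20 = sheet.point_at(20.0)
    ring_20 = rings.point_at(20.0)
    combined_20 = (
        dic_20.total("dicentric_equivalents")
        + ring_20.total("centric_rings")
        + ring_20.total("acentric_rings")
    ) / dic_20.n_cells
    fx = fixtures.fixation_time_sheets()
    yields = [
        _check("dicentric yield 0.1 Gy", dic_01.total("dicentric_equivalents") / dic_01.n_cells, 0.02),
        _check("dicentric yield 20 Gy", dic_20.total("dicentric_equivalents") / dic_20.n_cells, 13.75),
        _check("dicentrics+rings yield 20 Gy", combined_20, 14.98),
        _check("cal A 36 h, 2 Gy yield",
               fx["cal_a_36"].point_at(2.0).total("dicentric_equivalents") / 50, 0.44),
        _check("cal A 48 h, 4 Gy yield",
               fx["cal_a_48"].point_at(4.0).total("dicentric_equivalents") / 17, 1.82),
        _check("colcemid 48 h, 2 Gy yield",
               fx["colcemid_48"].point_at(2.0).total("dicentric_equivalents") / 100, 0.42),
    ]
    report["blocks"]["yields"] = yields

    # -- dose estimates ---------------------------------------------------
    curve = fixtures.fish_dicentric_curve()
    printed_est = fixtures.printed_dose_estimates()
    est_rows = []
    for rec in printed_est.itertuples():
        if rec.exposure_dose_gy == 0:
            continue  # the printed zero-dose cells are outside the checked set
        point = fx[rec.condition].point_at(float(rec.exposure_dose_gy))
        est = estimate_dose(curve, point.total("dicentric_equivalents"), point.n_cells)
        tag = f"{rec.condition} @ {rec.exposure_dose_gy:g} Gy"
        est_rows.append(_check(f"{tag} estimate", est.dose_gy, rec.estimate_gy))
        est_rows.append(_check(f"{tag} LCL", est.lcl_gy, rec.lcl_gy))
        est_rows.append(_check(f"{tag} UCL", est.ucl_gy, rec.ucl_gy))
    report["blocks"]["dose_estimates"] = est_rows

    # -- total-aberration yield correlations ------------------------------
    spectrum = fixtures.spectrum_table()
    corr_rows = []
    for donor in sorted(spectrum.donor.unique()):
        sub = spectrum[spectrum.donor == donor]
        meta = sub[sub.preparation == "METAPHASE"].sort_values("dose_gy")
        g2 = sub[sub.preparation == "G2_PCC"].sort_values("dose_gy")
        r = yield_correlation(
            (meta.printed_total / meta.cells_scored).to_numpy(),
            (g2.printed_total / g2.cells_scored).to_numpy(),
        )
        corr_rows.append(_check_ge(f"total-aberration r, {donor}", r, 0.99))
    report["blocks"]["correlations"] = corr_rows

    # -- prose ratios ------------------------------------------------------
    g2 = spectrum[spectrum.preparation == "G2_PCC"]
    ring_cols = ["centric_rings", "acentric_rings"]

    def ring_row(donor: str, dose: float):
        row = g2[(g2.donor == donor) & (g2.dose_gy == dose)].iloc[0]
        return int(sum(row[c] for c in ring_cols)), int(row.cells_scored)

    meta_d1 = spectrum[
        (spectrum.preparation == "METAPHASE")
        & (spectrum.donor == "donor1")
        & (spectrum.dose_gy == 7.5)
    ].iloc[0]
    frag = sum(meta_d1[c] for c in _FRAGMENTS)
    # single integer-ratio division avoids round-off on exact rationals
    (r2, n2), (r1, n1) = ring_row("donor2", 5.0), ring_row("donor1", 5.0)
    ratios = [
        _check_ge(
            "G2-PCC ring yield donor2/donor1 at 5 Gy",
            (r2 * n1) / (r1 * n2),
            1.6,
        ),
        _check_ge(
            "fragment/dicentric yield at 7.5 Gy (donor1 metaphase)",
            frag / meta_d1.dicentric_equivalents,
            1.6,
        ),
    ]
    report["blocks"]["ratios"] = ratios

    report["n_checks"] = sum(len(b) for b in report["blocks"].values())
    report["n_failed"] = sum(
        1 for b in report["blocks"].values() for row in b if not row["pass"]
    )
    report["all_pass"] = report["n_failed"] == 0
    return report


def format_report(report: dict) -> str:
    """Human-readable comparison table."""
    lines = []
    width = max(
        len(row["name"]) for block in report["blocks"].values() for row in block
    )
    for block_name, rows in report["blocks"].items():
        lines.append(f"== {block_name} ==")
        for row in rows:
            exp = row["expected"]
            exp_s = exp if isinstance(exp, str) else f"{exp:8.3f}"
            status = "ok" if row["pass"] else "FAIL"
            lines.append(
                f"  {row['name']:<{width}}  computed {row['computed']:8.3f}"
                f"  printed {exp_s}  [{status}]"
            )
    lines.append(
        f"{report['n_checks'] - report['n_failed']}/{report['n_checks']} checks passed"
    )
    return "\n".join(lines)
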