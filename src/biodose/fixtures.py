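"""Packaged study fixtures: the published score tables and calibration curves.

The package ships, as plain-text data, the per-dose dicentric count
distributions for calyculin-A induced G2-PCCs over 0-20 Gy of x-rays, the
ring totals, the six-category spectrum comparison between metaphases and
G2-PCCs for two donors, the dicentric totals for the fixation-time
comparison (calyculin A at 36 h and 48 h, colcemid at 48 h), the printed
dose estimates those counts produced, and the calibration curves involved.

Tables that print only per-dose totals (rings, spectrum, fixation-time) are
loaded as totals-only dose points; distribution-requiring statistics on
them report "unavailable" rather than imputing a distribution.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .lq_calibration import CalibrationCurve, read_curve
from .score_data import ABERRATION_CLASSES, DosePoint, ScoreSheet, read_score_sheet

__all__ = [
    "g2pcc_dicentric_sheet",
    "g2pcc_dicentric_printed_stats",
    "g2pcc_ring_sheet",
    "spectrum_table",
    "spectrum_sheets",
    "fixation_time_sheets",
    "printed_dose_estimates",
    "fish_dicentric_curve",
    "cabas_dicentric_curve",
    "cabas_ring_curve",
]

_DATA = resources.files("biodose") / "data"


def _path(name: str):
    return _DATA / name


def g2pcc_dicentric_sheet() -> ScoreSheet:
    """Dicentric count distributions in G2-PCCs, 14 doses from 0 to 20 Gy
    (the dose-response scoring experiment, female donor)."""
    with resources.as_file(_path("g2pcc_dicentric_distribution.csv")) as p:
        return read_score_sheet(
            p,
            "distribution_csv",
            preparation="G2_PCC",
            culture_hours=48.0,
            donor="donor_f1",
            sample_id="g2pcc_dicentrics_0_20Gy",
        )


def g2pcc_dicentric_printed_stats() -> pd.DataFrame:
    """The Yield/SE, Var-Mean/SE and U columns as printed (2 decimals)."""
    with resources.as_file(_path("g2pcc_dicentric_printed_stats.csv")) as p:
        return pd.read_csv(p)


def g2pcc_ring_sheet() -> ScoreSheet:
    """Ring totals (centric and acentric) in G2-PCCs; totals only, no
    per-cell distributions were published."""
    with resources.as_file(_path("g2pcc_ring_totals.csv")) as p:
        frame = pd.read_csv(p)
    points = [
        DosePoint(
            dose_gy=float(r.dose_gy),
            n_cells=int(r.cells_scored),
            totals={
                "centric_rings": int(r.centric_rings),
                "acentric_rings": int(r.acentric_rings),
            },
            preparation="G2_PCC",
            culture_hours=48.0,
            donor="donor_f1",
        )
        for r in frame.itertuples()
    ]
    return ScoreSheet(points=points, sample_id="g2pcc_rings_0_20Gy",
                      preparation="G2_PCC", donor="donor_f1")


def spectrum_table() -> pd.DataFrame:
    """Six-category aberration counts per (preparation, donor, dose) for the
    metaphase vs G2-PCC head-to-head comparison, with the printed totals."""
    with resources.as_file(_path("spectrum_comparison.csv")) as p:
        return pd.read_csv(p)


def spectrum_sheets() -> list[ScoreSheet]:
    """The spectrum comparison as four totals-only score sheets
    (2 preparations x 2 donors)."""
    frame = spectrum_table()
    sheets = []
    for (prep, donor), grp in frame.groupby(["preparation", "donor"]):
        points = [
            DosePoint(
                dose_gy=float(r.dose_gy),
                n_cells=int(r.cells_scored),
                totals={cls: int(getattr(r, cls)) for cls in ABERRATION_CLASSES},
                preparation=prep,
                culture_hours=48.0,
                donor=donor,
            )
            for r in grp.itertuples()
        ]
        sheets.append(
            ScoreSheet(points=points, sample_id=f"spectrum_{prep}_{donor}",
                       preparation=prep, culture_hours=48.0, donor=donor)
        )
    return sheets


def fixation_time_sheets() -> dict[str, ScoreSheet]:
    """Dicentric totals for the three culture conditions, keyed by condition
    (cal_a_36, cal_a_48, colcemid_48)."""
    with resources.as_file(_path("fixation_time_dicentrics.csv")) as p:
        frame = pd.read_csv(p)
    out: dict[str, ScoreSheet] = {}
    for cond, grp in frame.groupby("condition"):
        points = [
            DosePoint(
                dose_gy=float(r.dose_gy),
                n_cells=int(r.cells_scored),
                totals={"dicentric_equivalents": int(r.dicentric_equivalents)},
                preparation=r.preparation,
                culture_hours=float(r.culture_hours),
                donor="donor_f2",
            )
            for r in grp.itertuples()
        ]
        out[cond] = ScoreSheet(
            points=points,
            sample_id=f"fixation_{cond}",
            preparation=grp.preparation.iloc[0],
            culture_hours=float(grp.culture_hours.iloc[0]),
            donor="donor_f2",
        )
    return out


def printed_dose_estimates() -> pd.DataFrame:
    """Published dose estimates with 95% confidence limits, verbatim.

    ``delivered_dose_label`` is the label as printed; the last block is
    labelled "3" although the underlying exposures were 4 Gy, so
    ``exposure_dose_gy`` carries the actual exposure dose.
    """
    with resources.as_file(_path("printed_dose_estimates.csv")) as p:
        return pd.read_csv(p, dtype={"delivered_dose_label": str})


def fish_dicentric_curve() -> CalibrationCurve:
    """The laboratory FISH dicentric calibration curve used for dose
    estimation: Y = 0.008 + 0.088 D + 0.095 D^2."""
    with resources.as_file(_path("curve_fish_dicentrics.json")) as p:
        return read_curve(p)


def cabas_dicentric_curve() -> CalibrationCurve:
    """External CABAS dicentric coefficients (0, 0.021, 0.387).  Shipped as
    a reference fixture only: the regression protocol behind them is
    unstated and they are inconsistent with an LQ fit over the full 0-20 Gy
    distributions, so nothing in this package fits toward them."""
    with resources.as_file(_path("curve_cabas_dicentrics.json")) as p:
        return read_curve(p)


def cabas_ring_curve() -> CalibrationCurve:
    """External CABAS ring coefficients (0, 0.001, 0.051); same caveat as
    the CABAS dicentric curve."""
    with resources.as_file(_path("curve_cabas_rings.json")) as p:
        return read_curve(p)
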