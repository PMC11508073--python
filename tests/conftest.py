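import pytest

from biodose import CalibrationCurve, CellRecord, DosePoint, ScoreSheet


@pytest.fixture
def fish_curve() -> CalibrationCurve:
    """The dicentric calibration curve used for dose estimation,
    Y = 0.008 + 0.088 D + 0.095 D^2."""
    return CalibrationCurve(
        aberration_class="dicentric_equivalents",
        c=0.008,
        alpha=0.088,
        beta=0.095,
        se_c=0.004,
        se_alpha=0.022,
        se_beta=0.009,
    )


@pytest.fixture
def small_sheet() -> ScoreSheet:
    """A tiny hand-built per-cell sheet with two dose points."""
    cells_0 = [CellRecord(cell_id=f"a{i}") for i in range(5)]
    cells_2 = [
        CellRecord(cell_id="b1", dicentric_equivalents=1, compound_fragments=2),
        CellRecord(cell_id="b2", dicentric_equivalents=0, terminal_fragments=1),
        CellRecord(cell_id="b3", dicentric_equivalents=2, centric_rings=1),
        CellRecord(cell_id="b4"),
        CellRecord(cell_id="b5", dicentric_equivalents=1, interstitial_fragments=1),
    ]
    return ScoreSheet(
        points=[
            DosePoint(dose_gy=0.0, n_cells=5, cells=cells_0),
            DosePoint(dose_gy=2.0, n_cells=5, cells=cells_2),
        ],
        sample_id="tiny",
    )
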