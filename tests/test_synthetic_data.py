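import io
import math

import numpy as np
import pytest
from scipy import stats

from biodose import (
    CalibrationCurve,
    NegativeBinomialModel,
    PartialBodyModel,
    SimulationConfig,
    estimate_dose,
    fit_lq_poisson,
    fit_spectrum_model,
    simulate_score_sheet,
    simulate_study,
    write_score_sheet,
)
from biodose.dispersion_stats import summarize_dose_point
from biodose.score_data import ScoreSheetError
from biodose.spectrum_comparison import spectrum_design

DIC = "dicentric_equivalents"


def curve(c=0.0, alpha=0.021, beta=0.387):
    return CalibrationCurve(DIC, c, alpha, beta)


def config(**kw):
    defaults = dict(curves={DIC: curve()}, doses=[1.0], cells_per_dose=100, seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateScoreSheet:
    def test_zero_dose_zero_background_all_zero(self):
        sheet = simulate_score_sheet(config(doses=[0.0], cells_per_dose=500))
        assert all(c.total_aberrations == 0 for c in sheet.point_at(0.0).cells)

    def test_byte_identical_for_same_seed(self):
        cfg = config(doses=[0.0, 1.0, 3.0], cells_per_dose=200, seed=77)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_score_sheet(simulate_score_sheet(cfg), buf, "per_cell_csv")
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seeds_differ(self):
        a = simulate_score_sheet(config(seed=1))
        b = simulate_score_sheet(config(seed=2))
        assert a.point_at(1.0).total(DIC) != b.point_at(1.0).total(DIC) or (
            [c.dicentric_equivalents for c in a.point_at(1.0).cells]
            != [c.dicentric_equivalents for c in b.point_at(1.0).cells]
        )

    def test_empirical_yield_matches_curve(self):
        """At D=1 the empirical yield lies within 3 Monte-Carlo SEs of the
        LQ mean 0.408/cell."""
        cfg = config(cells_per_dose=10_000, seed=13)
        point = simulate_score_sheet(cfg).point_at(1.0)
        lam = 0.408
        assert point.total(DIC) / point.n_cells == pytest.approx(
            lam, abs=3 * math.sqrt(lam / 10_000)
        )

    def test_dispersion_index_near_one_under_poisson(self):
        """Mean Var/Mean over 500 seeded replicates is within 3 MC SEs of 1."""
        vms = []
        for seed in range(500):
            cfg = config(doses=[2.0], cells_per_dose=100, seed=seed)
            point = simulate_score_sheet(cfg).point_at(2.0)
            vms.append(summarize_dose_point(point).dispersion_index)
        vms = np.array(vms, dtype=float)
        mc_se = vms.std(ddof=1) / math.sqrt(len(vms))
        assert abs(vms.mean() - 1.0) < 3 * mc_se

    def test_negative_binomial_overdisperses(self):
        cfg = config(
            doses=[3.0],
            cells_per_dose=4000,
            seed=5,
            dispersion=NegativeBinomialModel(shape=2.0),
        )
        s = summarize_dose_point(simulate_score_sheet(cfg).point_at(3.0))
        lam = curve().evaluate(3.0)
        # Var/Mean should approach 1 + lam/shape, well above 1
        assert s.dispersion_index > 1.5
        assert s.dispersion_index == pytest.approx(1 + lam / 2.0, rel=0.15)

    def test_partial_body_mixture_overdisperses(self):
        cfg = config(
            doses=[4.0],
            cells_per_dose=4000,
            seed=6,
            dispersion=PartialBodyModel(fraction=0.5, background_yield=0.0),
        )
        point = simulate_score_sheet(cfg).point_at(4.0)
        s = summarize_dose_point(point)
        lam = curve().evaluate(4.0)
        assert s.yield_per_cell == pytest.approx(0.5 * lam, rel=0.1)
        assert s.u_statistic > 3  # mixture of exposed/unexposed cells

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ScoreSheetError):
            NegativeBinomialModel(shape=0.0)
        with pytest.raises(ScoreSheetError):
            PartialBodyModel(fraction=1.5)
        with pytest.raises(ScoreSheetError):
            config(cells_per_dose=0)
        with pytest.raises(ScoreSheetError):
            config(doses=[1.0, 1.0])

    def test_spectrum_proportions_split(self):
        props = {
            "dicentric_equivalents": 0.4,
            "centric_rings": 0.1,
            "compound_fragments": 0.5,
        }
        cfg = config(
            doses=[2.0],
            cells_per_dose=5000,
            seed=10,
            spectrum_proportions=props,
        )
        point = simulate_score_sheet(cfg).point_at(2.0)
        total = sum(point.total(cls) for cls in props)
        for cls, frac in props.items():
            assert point.total(cls) / total == pytest.approx(frac, abs=0.02)


class TestSimulateStudy:
    @staticmethod
    def arm(seed, donor="donor1", preparation="G2_PCC", shift=0.0, cells=100):
        props = np.array([0.35, 0.03, 0.02, 0.35, 0.15, 0.10])
        if shift:
            props = props * np.array([1, 1, 1, 1 + shift, 1 + shift, 1 + shift])
            props = props / props.sum()
        classes = [
            "dicentric_equivalents", "centric_rings", "acentric_rings",
            "compound_fragments", "terminal_fragments", "interstitial_fragments",
        ]
        return SimulationConfig(
            curves={"total": CalibrationCurve(DIC, 0.01, 0.1, 0.2)},
            doses=[0.5, 1.0, 2.0, 3.0],
            cells_per_dose=cells,
            seed=seed,
            spectrum_proportions=dict(zip(classes, props)),
            donor=donor,
            preparation=preparation,
        )

    def test_mismatched_dose_grids_rejected(self):
        a = self.arm(1)
        b = SimulationConfig(
            curves={DIC: curve()}, doses=[0.5, 1.0], cells_per_dose=50, seed=2,
            preparation="METAPHASE",
        )
        with pytest.raises(ScoreSheetError):
            simulate_study([a, b])

    def test_duplicate_arm_labels_rejected(self):
        with pytest.raises(ScoreSheetError):
            simulate_study([self.arm(1), self.arm(2)])

    def test_zero_cells_rejected(self):
        with pytest.raises(ScoreSheetError):
            self.arm(1, cells=0)

    def test_null_interaction_p_values_uniform(self):
        """With identical parameters in both arms the interaction Wald p is
        ~Uniform(0,1): Kolmogorov distance < 0.1 over 200 replicates."""
        ps = []
        for rep in range(200):
            sheets = simulate_study(
                [
                    self.arm(seed=1000 + 2 * rep, preparation="METAPHASE"),
                    self.arm(seed=1001 + 2 * rep, preparation="G2_PCC"),
                ]
            )
            fit = fit_spectrum_model(spectrum_design(sheets))
            row = fit.coefficients[
                (fit.coefficients.category == DIC)
                & (fit.coefficients.term == "dose_sq_x_g2")
            ].iloc[0]
            ps.append(row.p_value)
        ps = np.sort(ps)
        ecdf = np.arange(1, len(ps) + 1) / len(ps)
        ks = np.max(np.abs(ecdf - ps))
        assert ks < 0.1

    def test_fragment_shift_sign_recovered(self):
        """Tilting one arm's spectrum toward fragments flips the fragment
        share up (and the dicentric share down) in >= 95% of replicates."""
        hits = 0
        reps = 200
        for rep in range(reps):
            sheets = simulate_study(
                [
                    self.arm(seed=5000 + 2 * rep, preparation="METAPHASE"),
                    self.arm(seed=5001 + 2 * rep, preparation="G2_PCC", shift=0.6),
                ]
            )
            fit = fit_spectrum_model(
                spectrum_design(sheets), reference="dicentric_equivalents"
            )
            est, _ = fit.coefficient("compound_fragments", "dose_sq_x_g2")
            hits += est > 0
        assert hits >= 0.95 * reps


class TestEndToEndRecovery:
    def test_calibrate_then_estimate_covers_truth(self):
        """Simulate a calibration sheet at theta*, fit the LQ curve, then
        estimate dose from a fresh 2 Gy sample: the 95% CI contains 2 Gy in
        >= 90% of 200 seeded replicates."""
        true = CalibrationCurve(DIC, 0.005, 0.05, 0.08)
        doses = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0]
        hits = 0
        reps = 200
        for rep in range(reps):
            cal = simulate_score_sheet(
                SimulationConfig(
                    curves={DIC: true}, doses=doses, cells_per_dose=500,
                    seed=30_000 + 2 * rep,
                )
            )
            fitted = fit_lq_poisson(cal.points)
            fresh = simulate_score_sheet(
                SimulationConfig(
                    curves={DIC: true}, doses=[2.0], cells_per_dose=50,
                    seed=30_001 + 2 * rep,
                )
            )
            point = fresh.point_at(2.0)
            est = estimate_dose(fitted, point.total(DIC), point.n_cells)
            hits += est.lcl_gy <= 2.0 <= est.ucl_gy
        assert hits >= 0.90 * reps
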