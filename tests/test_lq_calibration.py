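import numpy as np
import pytest

from biodose import (
    CalibrationCurve,
    CellRecord,
    DosePoint,
    SimulationConfig,
    evaluate_curve,
    fit_lq_poisson,
    goodness_of_fit,
    read_curve,
    simulate_score_sheet,
    write_curve,
)
from biodose.lq_calibration import FitError
from biodose.score_data import ScoreSheetError


def totals_point(dose, x, n):
    return DosePoint(dose_gy=dose, n_cells=n, totals={"dicentric_equivalents": x})


def poisson_loglik(theta, d, x, n):
    lam = theta[0] + theta[1] * d + theta[2] * d * d
    return float(np.sum(x * np.log(n * lam) - n * lam))


class TestEvaluateInvariants:
    @pytest.mark.parametrize(
        "coeffs,dose,expected",
        [
            ((0.008, 0.088, 0.095), 0.0, 0.008),
            ((0.0, 0.021, 0.387), 1.0, 0.408),
            ((0.008, 0.088, 0.095), 2.0, 0.564),
        ],
    )
    def test_polynomial_values(self, coeffs, dose, expected):
        curve = CalibrationCurve("dicentric_equivalents", *coeffs)
        assert evaluate_curve(curve, dose) == pytest.approx(expected, abs=1e-12)

    def test_negative_dose_rejected(self, fish_curve):
        with pytest.raises(ValueError):
            fish_curve.evaluate(-0.5)

    def test_negative_beta_rejected(self):
        with pytest.raises(ScoreSheetError):
            CalibrationCurve("dicentric_equivalents", 0.0, 0.1, -0.01)

    def test_curve_json_round_trip(self, fish_curve, tmp_path):
        path = tmp_path / "curve.json"
        write_curve(fish_curve, path)
        back = read_curve(path)
        assert (back.c, back.alpha, back.beta) == (fish_curve.c, fish_curve.alpha, fish_curve.beta)
        assert back.se_alpha == fish_curve.se_alpha


class TestFit:
    def test_single_dose_closed_form(self):
        """With c and alpha absent (one dose, pure quadratic), the ML
        estimate is beta = X / (N D^2)."""
        points = [totals_point(2.0, 40, 100)]
        curve = fit_lq_poisson(points, fix_c_zero=True, fix_alpha_zero=True)
        assert curve.beta == pytest.approx(0.1, rel=1e-6)

    def test_noiseless_exact_recovery(self):
        """Data generated exactly on the curve are recovered to ~1e-6."""
        true = (0.01, 0.05, 0.06)
        n = 10**7  # huge N so rounding of expected counts is negligible
        points = [
            totals_point(d, round(n * (true[0] + true[1] * d + true[2] * d * d)), n)
            for d in (0.0, 1.0, 2.0, 4.0)
        ]
        curve = fit_lq_poisson(points)
        assert curve.c == pytest.approx(true[0], abs=1e-6)
        assert curve.alpha == pytest.approx(true[1], abs=1e-6)
        assert curve.beta == pytest.approx(true[2], abs=1e-6)

    def test_score_equations_hold_at_optimum(self):
        """sum_i N_i (X_i/(N_i lam_i) - 1) dlam/dtheta = 0 for each free
        parameter, to 1e-6."""
        curve, (d, x, n) = self._seeded_fit()
        lam = curve.evaluate(d)
        w = x / lam - n
        for deriv in (np.ones_like(d), d, d * d):
            assert abs(np.sum(w * deriv)) < 1e-6 * max(1.0, x.sum())

    def test_synthetic_recovery_and_grid_search_oracle(self):
        """On seeded Poisson data each estimate lies within 3 reported SEs of
        truth, and the fitted log-likelihood is within 1e-6 of the maximum
        over a 3-D lattice around the truth."""
        curve, (d, x, n) = self._seeded_fit()
        true = {"c": 0.001, "alpha": 0.02, "beta": 0.06}
        assert abs(curve.c - true["c"]) < 3 * curve.se_c
        assert abs(curve.alpha - true["alpha"]) < 3 * curve.se_alpha
        assert abs(curve.beta - true["beta"]) < 3 * curve.se_beta
        best = max(
            poisson_loglik((c, a, b), d, x, n)
            for c in np.linspace(1e-6, 0.004, 9)
            for a in np.linspace(0.005, 0.04, 11)
            for b in np.linspace(0.045, 0.075, 11)
        )
        fitted = poisson_loglik((curve.c, curve.alpha, curve.beta), d, x, n)
        assert fitted >= best - 1e-6

    @staticmethod
    def _seeded_fit():
        true = CalibrationCurve("dicentric_equivalents", 0.001, 0.02, 0.06)
        cfg = SimulationConfig(
            curves={"dicentric_equivalents": true},
            doses=[0.0, 0.5, 1.0, 2.0, 3.0, 5.0],
            cells_per_dose=5000,
            seed=7,
        )
        sheet = simulate_score_sheet(cfg)
        curve = fit_lq_poisson(sheet.points)
        d = np.array([p.dose_gy for p in sheet])
        x = np.array([p.total("dicentric") for p in sheet], dtype=float)
        n = np.array([p.n_cells for p in sheet], dtype=float)
        return curve, (d, x, n)

    def test_invariance_to_order_and_splitting(self):
        """The fit depends only on the per-dose sufficient statistics: it is
        unchanged by reordering dose points or splitting one into two with
        the same totals."""
        base = [
            totals_point(0.0, 2, 500),
            totals_point(1.0, 60, 400),
            totals_point(3.0, 300, 300),
            totals_point(5.0, 700, 250),
        ]
        ref = fit_lq_poisson(base)
        shuffled = fit_lq_poisson(base[::-1])
        # splitting the 3 Gy point (300 aberrations in 300 cells) into two halves
        split = [p for p in base if p.dose_gy != 3.0]
        split += [
            DosePoint(dose_gy=3.0, n_cells=150, totals={"dicentric_equivalents": 140}),
            DosePoint(dose_gy=3.0 + 1e-12, n_cells=150, totals={"dicentric_equivalents": 160}),
        ]
        halved = fit_lq_poisson(split)
        for other in (shuffled, halved):
            assert other.c == pytest.approx(ref.c, abs=1e-7)
            assert other.alpha == pytest.approx(ref.alpha, abs=1e-7)
            assert other.beta == pytest.approx(ref.beta, abs=1e-7)

    def test_parameter_recovery_rate(self):
        """Refitting data simulated from a fitted curve recovers each
        parameter within 3 SE in >= 95% of seeded replicates."""
        rng = np.random.default_rng(11)
        true = CalibrationCurve("dicentric_equivalents", 0.005, 0.05, 0.08)
        doses = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 5.0])
        n = 2000
        lam = true.evaluate(doses)
        hits = 0
        reps = 100
        for _ in range(reps):
            xs = rng.poisson(n * lam)
            points = [totals_point(d, int(x), n) for d, x in zip(doses, xs)]
            curve = fit_lq_poisson(points)
            ok = (
                abs(curve.c - true.c) <= 3 * curve.se_c
                and abs(curve.alpha - true.alpha) <= 3 * curve.se_alpha
                and abs(curve.beta - true.beta) <= 3 * curve.se_beta
            )
            hits += ok
        assert hits >= 0.95 * reps

    def test_too_few_points_rejected(self):
        with pytest.raises(ScoreSheetError):
            fit_lq_poisson([totals_point(1.0, 5, 100), totals_point(2.0, 20, 100)])

    def test_all_zero_counts_degenerate(self):
        points = [totals_point(d, 0, 100) for d in (0.0, 1.0, 2.0)]
        with pytest.raises(FitError):
            fit_lq_poisson(points)


class TestGoodnessOfFit:
    def test_noiseless_data_zero_deviance(self):
        true = CalibrationCurve("dicentric_equivalents", 0.01, 0.05, 0.06)
        n = 10**6
        points = [
            totals_point(d, round(n * true.evaluate(d)), n) for d in (0.0, 1.0, 2.0, 4.0)
        ]
        gof = goodness_of_fit(true, points)
        assert gof["deviance"] == pytest.approx(0.0, abs=1e-3)
        assert gof["df"] == 1

    def test_saturated_fit_df_undefined(self):
        true = CalibrationCurve("dicentric_equivalents", 0.01, 0.05, 0.06)
        points = [totals_point(d, 50, 100) for d in (1.0, 2.0, 3.0)]
        gof = goodness_of_fit(true, points)
        assert gof["df"] == 0 and gof["p_value"] is None

    def test_deviance_calibration_under_truth(self):
        """Simulated at the true curve, mean deviance/df ~ 1 over 200
        replicates (within 3 Monte-Carlo SEs)."""
        rng = np.random.default_rng(5)
        true = CalibrationCurve("dicentric_equivalents", 0.005, 0.05, 0.08)
        doses = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 5.0])
        n = 1000
        lam = true.evaluate(doses)
        ratios = []
        for _ in range(200):
            xs = rng.poisson(n * lam)
            points = [totals_point(d, int(x), n) for d, x in zip(doses, xs)]
            curve = fit_lq_poisson(points)
            gof = goodness_of_fit(curve, points)
            ratios.append(gof["deviance"] / gof["df"])
        ratios = np.array(ratios)
        mc_se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.0) < 3 * mc_se + 0.05
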