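"""Linear-quadratic dose-response calibration by Poisson maximum likelihood.

The yield of exchange-type aberrations per cell after acute photon exposure
follows the linear-quadratic (LQ) form

    Y(D) = c + alpha * D + beta * D**2

where c is the background yield per cell, alpha the one-track and beta the
two-track coefficient (per cell per Gy, per cell per Gy^2).  Given per-dose
totals (D_i, X_i, N_i) — the aggregated counts are sufficient under Poisson
scoring — the coefficients are fitted by maximising the Poisson
log-likelihood

    l(theta) = sum_i [ X_i * ln(N_i * Y(D_i)) - N_i * Y(D_i) ]

subject to theta >= 0, with standard errors from the inverse observed
information at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .score_data import DosePoint, ScoreSheetError, resolve_class

__all__ = [
    "CalibrationCurve",
    "FitError",
    "evaluate_curve",
    "fit_lq_poisson",
    "goodness_of_fit",
    "read_curve",
    "write_curve",
]

_LAMBDA_FLOOR = 1e-12  # guards ln(0) when a boundary parameter zeroes the mean


class FitError(RuntimeError):
    """Calibration fit failed; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class CalibrationCurve:
    """LQ dose-response coefficients with uncertainties and fit metadata."""

    aberration_class: str
    c: float
    alpha: float
    beta: float
    se_c: float | None = None
    se_alpha: float | None = None
    se_beta: float | None = None
    covariance: np.ndarray | None = None  # 3x3, order (c, alpha, beta)
    dose_unit: str = "Gy"
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.c < 0 or self.beta < 0:
            raise ScoreSheetError(
                f"curve coefficients c and beta must be >= 0 (got c={self.c}, beta={self.beta})"
            )
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (3, 3):
                raise ScoreSheetError(f"covariance must be 3x3, got shape {cov.shape}")
            # positive semidefinite up to round-off
            if np.min(np.linalg.eigvalsh((cov + cov.T) / 2)) < -1e-8 * max(1.0, np.abs(cov).max()):
                raise ScoreSheetError("covariance matrix is not positive semidefinite")
            self.covariance = cov

    def evaluate(self, dose_gy):
        """Predicted yield per cell, c + alpha*D + beta*D^2, for D >= 0."""
        d = np.asarray(dose_gy, dtype=float)
        if np.any(d < 0):
            raise ValueError(f"dose must be >= 0 {self.dose_unit}")
        y = self.c + self.alpha * d + self.beta * d * d
        return float(y) if np.isscalar(dose_gy) or d.ndim == 0 else y

    __call__ = evaluate


def evaluate_curve(curve: CalibrationCurve, dose_gy):
    return curve.evaluate(dose_gy)


# ---------------------------------------------------------------------------
# Curve file I/O (JSON)
# ---------------------------------------------------------------------------

def read_curve(path: str | Path) -> CalibrationCurve:
    with open(path, "r", encoding="utf-8") as fh:
        obj = json.load(fh)
    cov = obj.get("cov")
    return CalibrationCurve(
        aberration_class=resolve_class(obj["aberration_class"]),
        c=float(obj["c"]),
        alpha=float(obj["alpha"]),
        beta=float(obj["beta"]),
        se_c=None if obj.get("se_c") is None else float(obj["se_c"]),
        se_alpha=None if obj.get("se_alpha") is None else float(obj["se_alpha"]),
        se_beta=None if obj.get("se_beta") is None else float(obj["se_beta"]),
        covariance=None if cov is None else np.asarray(cov, dtype=float),
        dose_unit=obj.get("dose_unit", "Gy"),
        source=obj.get("source", ""),
    )


def write_curve(curve: CalibrationCurve, path: str | Path) -> None:
    obj = {
        "aberration_class": curve.aberration_class,
        "c": curve.c,
        "alpha": curve.alpha,
        "beta": curve.beta,
        "se_c": curve.se_c,
        "se_alpha": curve.se_alpha,
        "se_beta": curve.se_beta,
        "cov": None if curve.covariance is None else np.asarray(curve.covariance).tolist(),
        "dose_unit": curve.dose_unit,
        "source": curve.source,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _extract_totals(
    points: Iterable[DosePoint], cls: str, dose_range: tuple[float, float] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d, x, n = [], [], []
    for p in points:
        if dose_range is not None and not (dose_range[0] <= p.dose_gy <= dose_range[1]):
            continue
        d.append(p.dose_gy)
        x.append(p.total(cls))
        n.append(p.n_cells)
    return np.asarray(d, float), np.asarray(x, float), np.asarray(n, float)


def fit_lq_poisson(
    points: Sequence[DosePoint],
    aberration_class: str = "dicentric_equivalents",
    *,
    fix_c_zero: bool = False,
    fix_alpha_zero: bool = False,
    dose_range: tuple[float, float] | None = None,
    max_iter: int = 200,
    grad_tol: float = 1e-8,
) -> CalibrationCurve:
    """Fit Y(D) = c + alpha*D + beta*D^2 to per-dose totals by Poisson ML.

    Parameters are constrained non-negative; standard errors come from the
    inverse observed information.  When an estimate sits on the zero
    boundary its SE is flagged unreliable in ``metadata['boundary']``.

    Starting values come from unweighted least squares on the observed
    yields, projected onto the non-negative orthant.
    """
    cls = resolve_class(aberration_class)
    d, x, n = _extract_totals(points, cls, dose_range)
    n_free_coef = 3 - int(fix_c_zero) - int(fix_alpha_zero)
    if len(d) < n_free_coef:
        raise ScoreSheetError(
            f"need >= {n_free_coef} dose points to fit {n_free_coef} free parameters, got {len(d)}"
        )
    if x.sum() == 0:
        raise FitError("degenerate fit: all aberration counts are zero")

    # Design matrix of free parameters: lambda = V @ theta
    cols = {"c": np.ones_like(d), "alpha": d, "beta": d * d}
    if fix_c_zero:
        del cols["c"]
    if fix_alpha_zero:
        del cols["alpha"]
    names = list(cols)
    v = np.column_stack(list(cols.values()))
    p = v.shape[1]

    def nll(theta: np.ndarray) -> float:
        lam = np.maximum(v @ theta, _LAMBDA_FLOOR)
        return float(np.sum(n * lam) - np.sum(x * np.log(n * lam)))

    def grad(theta: np.ndarray) -> np.ndarray:
        lam = np.maximum(v @ theta, _LAMBDA_FLOOR)
        w = n - x / lam
        return v.T @ w

    # Start: least squares on yields, clipped into the feasible region.
    y_obs = x / n
    theta0, *_ = np.linalg.lstsq(v, y_obs, rcond=None)
    theta0 = np.maximum(theta0, 1e-6)

    res = optimize.minimize(
        nll,
        theta0,
        jac=grad,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * p,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": grad_tol},
    )
    theta = res.x
    gnorm = float(np.linalg.norm(grad(theta), ord=np.inf))
    boundary = [names[i] for i in range(p) if theta[i] <= 1e-9]
    # At an active bound the projected gradient, not the raw gradient,
    # should vanish; judge convergence on the free components.
    free = np.array([theta[i] > 1e-9 for i in range(p)])
    gnorm_free = float(np.linalg.norm(grad(theta)[free], ord=np.inf)) if free.any() else 0.0
    if not res.success and gnorm_free > 1e-4 * max(1.0, x.sum()):
        raise FitError(
            f"LQ Poisson fit did not converge: {res.message}",
            {"iterations": res.nit, "grad_norm": gnorm, "theta": theta.tolist()},
        )

    # Observed information: H = sum_i X_i / lambda_i^2 * v_i v_i^T
    lam = np.maximum(v @ theta, _LAMBDA_FLOOR)
    h = (v * (x / lam**2)[:, None]).T @ v
    try:
        cov_free = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        cov_free = np.linalg.pinv(h)
    se_free = np.sqrt(np.maximum(np.diag(cov_free), 0.0))

    full = {"c": 0.0, "alpha": 0.0, "beta": 0.0}
    se = {"c": 0.0, "alpha": 0.0, "beta": 0.0}
    cov3 = np.zeros((3, 3))
    idx3 = {"c": 0, "alpha": 1, "beta": 2}
    for i, name in enumerate(names):
        full[name] = float(theta[i])
        se[name] = float(se_free[i])
        for j, name2 in enumerate(names):
            cov3[idx3[name], idx3[name2]] = cov_free[i, j]

    loglik = -nll(theta)  # up to the data-only constant sum ln(X_i!)
    return CalibrationCurve(
        aberration_class=cls,
        c=full["c"],
        alpha=full["alpha"],
        beta=full["beta"],
        se_c=se["c"],
        se_alpha=se["alpha"],
        se_beta=se["beta"],
        covariance=cov3,
        source="fit_lq_poisson",
        metadata={
            "doses": d.tolist(),
            "cells": n.tolist(),
            "counts": x.tolist(),
            "fix_c_zero": fix_c_zero,
            "fix_alpha_zero": fix_alpha_zero,
            "free_parameters": names,
            "log_likelihood": loglik,
            "iterations": int(res.nit),
            "grad_norm": gnorm,
            "converged": bool(res.success or gnorm_free <= 1e-4 * max(1.0, x.sum())),
            "boundary": boundary,
        },
    )


def goodness_of_fit(
    curve: CalibrationCurve,
    points: Sequence[DosePoint],
    aberration_class: str | None = None,
    *,
    dose_range: tuple[float, float] | None = None,
) -> dict:
    """Poisson deviance of a fitted curve against per-dose totals.

    deviance = 2 * sum_i [ X_i ln(X_i / mu_i) - (X_i - mu_i) ] with
    mu_i = N_i * Y(D_i); df = n_doses - n_free_parameters.  The p-value is
    the upper chi-square tail, or ``None`` when df <= 0 (saturated fit).
    """
    cls = resolve_class(aberration_class or curve.aberration_class)
    d, x, n = _extract_totals(points, cls, dose_range)
    mu = n * np.maximum(curve.evaluate(d), _LAMBDA_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / mu), 0.0)
    deviance = float(2.0 * np.sum(term - (x - mu)))
    free = curve.metadata.get("free_parameters")
    n_free = len(free) if free is not None else 3
    df = len(d) - n_free
    p_value = float(stats.chi2.sf(deviance, df)) if df > 0 else None
    return {"deviance": deviance, "df": df, "p_value": p_value}
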