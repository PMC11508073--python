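"""Aberration-spectrum comparison between chromosome preparations.

Models the six-category aberration spectrum (dicentric equivalents,
centric/acentric rings, compound/terminal/interstitial fragments) at each
design point (dose x donor x preparation) as a multinomial draw, with a
baseline-category logit link.  For non-reference category k the linear
predictor is

    eta_k = a_k + d_k * donor + b_k * D^2 + g_k * D^2 * G2

where G2 is 1 for calyculin-A induced G2-PCC preparations and 0 for
colcemid-arrested metaphases.  Dose enters through D^2 only (the two-track
term of the LQ model); with few dose levels the linear term is not
separately identifiable from the intercept shift and is omitted.  The
interaction g_k asks whether the dose response of category k's share
differs between preparations.  Wald z tests are reported per coefficient;
the covariance is the inverse observed information.

Counts are aggregated per design point; the multinomial likelihood depends
on the data only through those totals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .score_data import ABERRATION_CLASSES, ScoreSheet, ScoreSheetError

__all__ = [
    "SpectrumFit",
    "spectrum_design",
    "fit_spectrum_model",
    "wald_test",
    "yield_correlation",
]


def spectrum_design(sheets: Iterable[ScoreSheet]) -> pd.DataFrame:
    """Build the design table from score sheets: one row per
    (dose, donor, preparation) with aggregated category counts."""
    rows = []
    for sheet in sheets:
        for point in sheet:
            row = {
                "dose_gy": point.dose_gy,
                "donor": point.donor,
                "g2": 1 if point.preparation == "G2_PCC" else 0,
            }
            for cls in ABERRATION_CLASSES:
                row[cls] = point.total(cls)
            rows.append(row)
    frame = pd.DataFrame(rows)
    return (
        frame.groupby(["dose_gy", "donor", "g2"], as_index=False)[list(ABERRATION_CLASSES)]
        .sum()
    )


@dataclass
class SpectrumFit:
    """Fitted multinomial spectrum model."""

    categories: list[str]           # modelled categories, reference last
    reference: str
    terms: list[str]                # per-category regressor names
    coefficients: pd.DataFrame      # category, term, estimate, se, z, p_value
    covariance: np.ndarray          # over the flattened (category x term) params
    log_likelihood: float
    n_obs: int
    converged: bool
    design: pd.DataFrame = field(repr=False, default=None)
    _beta: np.ndarray = field(repr=False, default=None)  # (K-1, T)
    _xcols: list[str] = field(repr=False, default_factory=list)

    def coefficient(self, category: str, term: str) -> tuple[float, float]:
        """(estimate, se) for one coefficient."""
        sel = self.coefficients[
            (self.coefficients.category == category) & (self.coefficients.term == term)
        ]
        if sel.empty:
            raise KeyError(f"no coefficient ({category!r}, {term!r})")
        row = sel.iloc[0]
        return float(row.estimate), float(row.se)

    def predict_proba(self, design: pd.DataFrame | None = None) -> pd.DataFrame:
        """Fitted category probabilities at each design point (rows sum to 1)."""
        frame = self.design if design is None else design
        x = _design_matrix(frame, self._xcols)
        eta = x @ self._beta.T                      # (n, K-1)
        eta = np.column_stack([eta, np.zeros(len(frame))])  # reference
        p = np.exp(eta - eta.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, columns=self.categories, index=frame.index)


def _design_matrix(frame: pd.DataFrame, xcols: list[str]) -> np.ndarray:
    cols = []
    for name in xcols:
        if name == "intercept":
            cols.append(np.ones(len(frame)))
        elif name == "dose_sq":
            cols.append(frame["dose_gy"].to_numpy(float) ** 2)
        elif name == "dose_sq_x_g2":
            cols.append(frame["dose_gy"].to_numpy(float) ** 2 * frame["g2"].to_numpy(float))
        elif name.startswith("donor:"):
            cols.append((frame["donor"] == name.split(":", 1)[1]).to_numpy(float))
        else:
            raise ScoreSheetError(f"unknown design term {name!r}")
    return np.column_stack(cols)


def fit_spectrum_model(
    design: pd.DataFrame,
    reference: str = "compound_fragments",
    *,
    include_donor: bool | None = None,
    include_interaction: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SpectrumFit:
    """Fit the multinomial logit spectrum model to an aggregated design table.

    ``design`` needs columns ``dose_gy``, ``donor``, ``g2`` plus one count
    column per aberration category.  All-zero categories are dropped with a
    warning.  Newton-Raphson with step halving on the multinomial
    log-likelihood; analytic gradient and Hessian.
    """
    cats = [c for c in ABERRATION_CLASSES if c in design.columns]
    if not cats:
        raise ScoreSheetError("design table has no aberration-category columns")
    counts = design[cats].to_numpy(float)
    if np.any(counts < 0):
        raise ScoreSheetError("category counts must be >= 0")
    nonzero = counts.sum(axis=0) > 0
    if not nonzero.all():
        dropped = [c for c, keep in zip(cats, nonzero) if not keep]
        warnings.warn(f"dropping empty aberration categories: {dropped}")
        cats = [c for c, keep in zip(cats, nonzero) if keep]
        counts = design[cats].to_numpy(float)
    if reference not in cats:
        reference = max(cats, key=lambda c: design[c].sum())
    cats = [c for c in cats if c != reference] + [reference]
    counts = design[cats].to_numpy(float)

    g2_levels = sorted(design["g2"].unique())
    doses = design["dose_gy"].unique()
    xcols = ["intercept"]
    donors = sorted(design["donor"].astype(str).unique())
    if include_donor is None:
        include_donor = len(donors) > 1
    if include_donor:
        xcols += [f"donor:{d}" for d in donors[1:]]
    xcols.append("dose_sq")
    if include_interaction:
        if len(g2_levels) < 2 or len(doses) < 2:
            raise ScoreSheetError(
                "interaction term needs both preparation levels and >= 2 doses"
            )
        xcols.append("dose_sq_x_g2")

    x = _design_matrix(design, xcols)
    n_obs, t = x.shape
    k = len(cats)
    m = counts.sum(axis=1)  # per-observation totals
    n_par = (k - 1) * t

    def unpack(theta: np.ndarray) -> np.ndarray:
        return theta.reshape(k - 1, t)

    def probs(beta: np.ndarray) -> np.ndarray:
        eta = np.column_stack([x @ beta.T, np.zeros(n_obs)])
        p = np.exp(eta - eta.max(axis=1, keepdims=True))
        return p / p.sum(axis=1, keepdims=True)

    def loglik(theta: np.ndarray) -> float:
        p = probs(unpack(theta))
        with np.errstate(divide="ignore"):
            lp = np.where(counts > 0, counts * np.log(np.maximum(p, 1e-300)), 0.0)
        return float(lp.sum())

    def grad_hess(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = unpack(theta)
        p = probs(beta)  # (n, K)
        resid = counts[:, : k - 1] - m[:, None] * p[:, : k - 1]  # (n, K-1)
        g = (x.T @ resid).T.ravel()  # d l / d beta_kj, category-major
        h = np.zeros((n_par, n_par))
        xxt = x[:, :, None] * x[:, None, :]  # (n, T, T)
        for a in range(k - 1):
            for b in range(a, k - 1):
                w = m * p[:, a] * ((1.0 if a == b else 0.0) - p[:, b])
                block = np.tensordot(w, xxt, axes=(0, 0))
                h[a * t : (a + 1) * t, b * t : (b + 1) * t] = block
                if a != b:
                    h[b * t : (b + 1) * t, a * t : (a + 1) * t] = block.T
        return g, h  # h is the *negative* Hessian of l (Fisher information form)

    theta = np.zeros(n_par)
    ll = loglik(theta)
    converged = False
    for _ in range(max_iter):
        g, h = grad_hess(theta)
        try:
            step = np.linalg.solve(h + 1e-10 * np.eye(n_par), g)
        except np.linalg.LinAlgError:
            raise ScoreSheetError("spectrum fit failed: singular information matrix "
                                  "(possible separation)")
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        improved = ll_new - ll
        theta, ll = cand, ll_new
        if improved < tol * (abs(ll) + 1.0) and np.linalg.norm(g, np.inf) < 1e-6 * (m.sum() + 1):
            converged = True
            break
    g, h = grad_hess(theta)
    if not converged and np.linalg.norm(g, np.inf) < 1e-4 * (m.sum() + 1):
        converged = True
    if not converged:
        raise ScoreSheetError(
            f"spectrum fit did not converge in {max_iter} iterations "
            f"(|grad|_inf = {np.linalg.norm(g, np.inf):.3g}); possible separation"
        )
    cov = np.linalg.pinv(h)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    beta = unpack(theta)
    rows = []
    for a, cat in enumerate(cats[:-1]):
        for j, term in enumerate(xcols):
            est = beta[a, j]
            s = se[a * t + j]
            w = wald_test(est, s) if s > 0 else {"z": float("nan"), "p_value": float("nan")}
            rows.append(
                {"category": cat, "term": term, "estimate": est, "se": s,
                 "z": w["z"], "p_value": w["p_value"]}
            )
    table = pd.DataFrame(rows)
    return SpectrumFit(
        categories=cats,
        reference=reference,
        terms=xcols,
        coefficients=table,
        covariance=cov,
        log_likelihood=ll,
        n_obs=n_obs,
        converged=converged,
        design=design.reset_index(drop=True),
        _beta=beta,
        _xcols=xcols,
    )


def wald_test(estimate: float, se: float) -> dict:
    """Two-sided Wald test: z = estimate/se, p from the standard normal."""
    if not se > 0:
        raise ScoreSheetError(f"Wald test needs se > 0, got {se}")
    z = estimate / se
    return {"z": float(z), "p_value": float(2.0 * stats.norm.sf(abs(z)))}


def yield_correlation(yields_a: Sequence[float], yields_b: Sequence[float]) -> float:
    """Pearson product-moment correlation between two per-dose yield series.

    Returns NaN (undefined) when either series has zero variance.
    """
    a = np.asarray(yields_a, float)
    b = np.asarray(yields_b, float)
    if a.shape != b.shape:
        raise ScoreSheetError(f"yield series differ in length: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ScoreSheetError(f"need >= 3 paired doses, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)
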