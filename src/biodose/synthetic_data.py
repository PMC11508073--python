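"""Synthetic score-sheet generator.

Emulates the statistical structure the analysis chain assumes: per-cell
aberration counts drawn around a linear-quadratic mean yield per dose, with
one independent stream per aberration class (no co-occurrence structure is
modelled — published tables report only marginal counts, so independence is
the explicit simplifying assumption).  Three per-cell dispersion models:

* ``PoissonModel`` — counts ~ Poisson(lambda(D)); Var/Mean = 1, the
  whole-body photon-exposure reference case;
* ``NegativeBinomialModel(shape)`` — gamma-mixed Poisson with
  Var = lambda + lambda^2/shape, i.e. overdispersion that vanishes as
  shape -> infinity;
* ``PartialBodyModel(fraction, background_yield)`` — each cell comes from
  the irradiated fraction (mean lambda(D)) or the unexposed remainder
  (mean background), a two-component mixture without cell-death weighting
  (a deliberate simplification).

Alternatively a single total-aberration curve plus fixed spectrum
proportions draws a per-cell total and splits it multinomially across the
six categories.

Every stochastic run requires an explicit seed; identical seed and config
give byte-identical sheets (numpy PCG64 generator, recorded in the sheet
sample id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .lq_calibration import CalibrationCurve
from .score_data import (
    ABERRATION_CLASSES,
    CellRecord,
    DosePoint,
    ScoreSheet,
    ScoreSheetError,
    resolve_class,
)

__all__ = [
    "PoissonModel",
    "NegativeBinomialModel",
    "PartialBodyModel",
    "SimulationConfig",
    "simulate_score_sheet",
    "simulate_study",
]


@dataclass(frozen=True)
class PoissonModel:
    name: str = "poisson"


@dataclass(frozen=True)
class NegativeBinomialModel:
    """Overdispersed counts: Var = mean + mean^2 / shape."""

    shape: float
    name: str = "neg_binomial"

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ScoreSheetError(f"negative-binomial shape must be > 0, got {self.shape}")


@dataclass(frozen=True)
class PartialBodyModel:
    """Mixture: a cell is irradiated with probability ``fraction`` (mean
    lambda(D)), otherwise unexposed (mean ``background_yield``)."""

    fraction: float
    background_yield: float = 0.0
    name: str = "partial_body"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ScoreSheetError(f"irradiated fraction must be in (0, 1], got {self.fraction}")
        if self.background_yield < 0:
            raise ScoreSheetError("background yield must be >= 0")


DispersionModel = PoissonModel | NegativeBinomialModel | PartialBodyModel


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated score sheet.

    ``curves`` maps aberration classes to their LQ dose-response curves; with
    ``spectrum_proportions`` given, a single curve (any key) sets the total
    aberration yield and the proportions split it across classes.
    """

    curves: Mapping[str, CalibrationCurve]
    doses: Sequence[float]
    cells_per_dose: int
    seed: int
    dispersion: DispersionModel = PoissonModel()
    spectrum_proportions: Mapping[str, float] | None = None
    preparation: str = "G2_PCC"
    culture_hours: float = 48.0
    donor: str = "donor1"
    sample_id: str = "simulated"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ScoreSheetError("a seed is mandatory for every stochastic run")
        if self.cells_per_dose < 1:
            raise ScoreSheetError(f"cells_per_dose must be >= 1, got {self.cells_per_dose}")
        if any(d < 0 for d in self.doses):
            raise ScoreSheetError("doses must be >= 0 Gy")
        if len(set(self.doses)) != len(tuple(self.doses)):
            raise ScoreSheetError("doses must be unique")
        if not self.curves:
            raise ScoreSheetError("at least one calibration curve is required")
        if self.spectrum_proportions is not None:
            props = {resolve_class(k): float(v) for k, v in self.spectrum_proportions.items()}
            if any(v < 0 for v in props.values()):
                raise ScoreSheetError("spectrum proportions must be >= 0")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ScoreSheetError(f"spectrum proportions must sum to 1, got {total}")
            if len(self.curves) != 1:
                raise ScoreSheetError(
                    "with spectrum_proportions give exactly one (total-yield) curve"
                )
            object.__setattr__(self, "spectrum_proportions", props)
        else:
            object.__setattr__(
                self, "curves", {resolve_class(k): v for k, v in self.curves.items()}
            )


def _draw_counts(
    rng: np.random.Generator, model: DispersionModel, lam: float, background: float, n: int
) -> np.ndarray:
    """n per-cell counts with mean yield lam under the dispersion model."""
    if isinstance(model, PoissonModel):
        return rng.poisson(lam, size=n)
    if isinstance(model, NegativeBinomialModel):
        if lam <= 0:
            return np.zeros(n, dtype=np.int64)
        p = model.shape / (model.shape + lam)
        return rng.negative_binomial(model.shape, p, size=n)
    if isinstance(model, PartialBodyModel):
        irradiated = rng.random(n) < model.fraction
        means = np.where(irradiated, lam, model.background_yield)
        return rng.poisson(means)
    raise ScoreSheetError(f"unknown dispersion model {model!r}")


def simulate_score_sheet(config: SimulationConfig) -> ScoreSheet:
    """Simulate one score sheet under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    points: list[DosePoint] = []
    n = config.cells_per_dose
    for dose in config.doses:
        if config.spectrum_proportions is not None:
            (curve,) = config.curves.values()
            totals = _draw_counts(rng, config.dispersion, curve.evaluate(dose), curve.c, n)
            classes = list(config.spectrum_proportions)
            pvals = np.array([config.spectrum_proportions[c] for c in classes])
            split = rng.multinomial(totals, pvals)  # (n, len(classes))
            per_class = dict(zip(classes, split.T))
        else:
            per_class = {
                cls: _draw_counts(rng, config.dispersion, curve.evaluate(dose), curve.c, n)
                for cls, curve in config.curves.items()
            }
        cells = []
        for i in range(n):
            counts = {cls: int(arr[i]) for cls, arr in per_class.items()}
            cells.append(CellRecord(cell_id=f"d{dose:g}-c{i + 1}", **counts))
        points.append(
            DosePoint(
                dose_gy=float(dose),
                n_cells=n,
                cells=cells,
                preparation=config.preparation,
                culture_hours=config.culture_hours,
                donor=config.donor,
            )
        )
    return ScoreSheet(
        points=points,
        sample_id=f"{config.sample_id}[pcg64:{config.seed}]",
        preparation=config.preparation,
        culture_hours=config.culture_hours,
        donor=config.donor,
    )


def simulate_study(configs: Sequence[SimulationConfig]) -> list[ScoreSheet]:
    """Simulate a multi-arm study (e.g. two preparations x two donors).

    All arms must share the same dose grid and carry distinct
    (donor, preparation) labels; each arm uses its own seed.  With identical
    parameters in every arm, preparation effects are null by construction.
    """
    if not configs:
        raise ScoreSheetError("simulate_study needs at least one arm")
    grids = {tuple(cfg.doses) for cfg in configs}
    if len(grids) != 1:
        raise ScoreSheetError(f"all arms must share one dose grid, got {sorted(grids)}")
    labels = [(cfg.donor, cfg.preparation) for cfg in configs]
    if len(set(labels)) != len(labels):
        raise ScoreSheetError(f"duplicate (donor, preparation) arms: {labels}")
    return [simulate_score_sheet(cfg) for cfg in configs]
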