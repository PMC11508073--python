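"""Data model, classification rules and I/O for cytogenetic score sheets.

A *score sheet* records, per radiation dose, the unstable chromosome
aberrations counted in individual cells (metaphase spreads or calyculin-A
induced G2-PCC spreads) after centromere/telomere FISH staining.  Six
aberration categories are distinguished:

* dicentric equivalents — dicentrics plus multicentrics, a chromosome with
  C centromeres counting as C-1 dicentrics;
* centric and acentric rings — ring chromosomes with/without a centromeric
  signal;
* compound, terminal and interstitial fragments — acentric fragments with a
  telomeric signal at both ends, one end, or neither end.

Two plain-text dialects are supported: a per-cell CSV (one row per scored
cell) and a long-form distribution CSV (one row per dose x class x count,
the shape of a published count-distribution table).  Per-cell storage is
canonical; distributions are an aggregated view.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ABERRATION_CLASSES",
    "PREPARATIONS",
    "CellRecord",
    "MulticentricEvent",
    "DosePoint",
    "ScoreSheet",
    "ScoreSheetError",
    "ParseError",
    "DistributionUnavailableError",
    "dicentric_equivalents",
    "aggregate_distribution",
    "resolve_class",
    "read_score_sheet",
    "write_score_sheet",
]

#: Canonical aberration category names, in score-sheet column order.
ABERRATION_CLASSES: tuple[str, ...] = (
    "dicentric_equivalents",
    "centric_rings",
    "acentric_rings",
    "compound_fragments",
    "terminal_fragments",
    "interstitial_fragments",
)

PREPARATIONS: tuple[str, ...] = ("G2_PCC", "METAPHASE")

_CLASS_ALIASES: dict[str, str] = {
    "dicentric": "dicentric_equivalents",
    "dicentrics": "dicentric_equivalents",
    "dic": "dicentric_equivalents",
    "centric_ring": "centric_rings",
    "acentric_ring": "acentric_rings",
    "compound": "compound_fragments",
    "terminal": "terminal_fragments",
    "interstitial": "interstitial_fragments",
}


class ScoreSheetError(ValueError):
    """Invalid score-sheet content or structure."""


class ParseError(ScoreSheetError):
    """Malformed score-sheet file; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


class DistributionUnavailableError(ScoreSheetError):
    """A per-cell count distribution was requested but only totals exist."""


def resolve_class(name: str) -> str:
    """Map a user-facing class name (e.g. ``"dicentric"``) to its canonical
    column name, validating it."""
    key = name.strip().lower()
    key = _CLASS_ALIASES.get(key, key)
    if key not in ABERRATION_CLASSES:
        raise ScoreSheetError(
            f"unknown aberration class {name!r}; expected one of "
            f"{ABERRATION_CLASSES} or an alias like 'dicentric'"
        )
    return key


def _check_count(value: object, what: str) -> int:
    if isinstance(value, bool) or not isinstance(value, int):
        try:
            ivalue = int(value)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ScoreSheetError(f"{what} must be an integer, got {value!r}")
        if ivalue != value:
            raise ScoreSheetError(f"{what} must be an integer, got {value!r}")
        value = ivalue
    if value < 0:
        raise ScoreSheetError(f"{what} must be >= 0, got {value}")
    return value


@dataclass(frozen=True)
class CellRecord:
    """Aberration counts scored in one cell, multicentrics already converted
    to dicentric equivalents."""

    cell_id: str
    dicentric_equivalents: int = 0
    centric_rings: int = 0
    acentric_rings: int = 0
    compound_fragments: int = 0
    terminal_fragments: int = 0
    interstitial_fragments: int = 0

    def __post_init__(self) -> None:
        for name in ABERRATION_CLASSES:
            object.__setattr__(
                self, name, _check_count(getattr(self, name), f"{name} of cell {self.cell_id!r}")
            )

    def count(self, aberration_class: str) -> int:
        return int(getattr(self, resolve_class(aberration_class)))

    @property
    def total_aberrations(self) -> int:
        return sum(getattr(self, name) for name in ABERRATION_CLASSES)


@dataclass(frozen=True)
class MulticentricEvent:
    """A chromosome with two or more centromeres observed in one cell.

    A chromosome carrying C centromeres arises from C-1 pairwise exchange
    events and therefore contributes C-1 dicentric equivalents (a tricentric
    counts as two dicentrics).
    """

    n_centromeres: int

    def __post_init__(self) -> None:
        n = _check_count(self.n_centromeres, "n_centromeres")
        if n < 2:
            raise ScoreSheetError(f"a multicentric event needs >= 2 centromeres, got {n}")
        object.__setattr__(self, "n_centromeres", n)

    @property
    def dicentric_equivalents(self) -> int:
        return self.n_centromeres - 1


def dicentric_equivalents(events: Iterable[MulticentricEvent]) -> int:
    """Total dicentric equivalents of a collection of (multi)centric
    exchange chromosomes: sum of (centromeres - 1) over events."""
    total = 0
    for ev in events:
        if not isinstance(ev, MulticentricEvent):
            ev = MulticentricEvent(ev)  # accept raw centromere counts
        total += ev.dicentric_equivalents
    return total


def aggregate_distribution(
    cells: Sequence[CellRecord], aberration_class: str = "dicentric_equivalents"
) -> dict[int, int]:
    """Aggregate per-cell counts of one class into a count->cells mapping.

    The result conserves both the number of cells (sum of values) and the
    class total (sum of count*cells).
    """
    if not cells:
        raise ScoreSheetError("cannot aggregate an empty cell list")
    cls = resolve_class(aberration_class)
    dist = Counter(getattr(c, cls) for c in cells)
    return dict(sorted(dist.items()))


@dataclass
class DosePoint:
    """All cells scored at one dose level, in one of three representations:
    an explicit per-cell list, per-class count distributions, or per-class
    totals only (as printed in summary tables).

    Whichever representations are present must agree on the number of cells
    and class totals; this is validated at construction.
    """

    dose_gy: float
    n_cells: int
    cells: list[CellRecord] | None = None
    distributions: dict[str, dict[int, int]] | None = None
    totals: dict[str, int] | None = None
    preparation: str = "G2_PCC"
    culture_hours: float = 48.0
    donor: str = "donor1"

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ScoreSheetError(f"dose must be >= 0 Gy, got {self.dose_gy}")
        if self.n_cells < 1:
            raise ScoreSheetError(f"a dose point needs >= 1 scored cell, got {self.n_cells}")
        if self.preparation not in PREPARATIONS:
            raise ScoreSheetError(
                f"preparation must be one of {PREPARATIONS}, got {self.preparation!r}"
            )
        if self.cells is None and self.distributions is None and self.totals is None:
            raise ScoreSheetError("dose point needs cells, distributions or totals")
        if self.cells is not None and len(self.cells) != self.n_cells:
            raise ScoreSheetError(
                f"dose {self.dose_gy} Gy: n_cells={self.n_cells} but {len(self.cells)} "
                "cell records given"
            )
        if self.distributions is not None:
            clean: dict[str, dict[int, int]] = {}
            for cls, dist in self.distributions.items():
                cls = resolve_class(cls)
                dist = {
                    _check_count(k, f"count in {cls} distribution"): _check_count(
                        v, f"cell number in {cls} distribution"
                    )
                    for k, v in dist.items()
                }
                n = sum(dist.values())
                if n != self.n_cells:
                    raise ScoreSheetError(
                        f"dose {self.dose_gy} Gy, class {cls}: distribution covers {n} "
                        f"cells but n_cells={self.n_cells}"
                    )
                clean[cls] = dict(sorted(dist.items()))
                if self.cells is not None and clean[cls] != aggregate_distribution(self.cells, cls):
                    raise ScoreSheetError(
                        f"dose {self.dose_gy} Gy, class {cls}: stored distribution "
                        "disagrees with the per-cell records"
                    )
            self.distributions = clean
        if self.totals is not None:
            self.totals = {
                resolve_class(k): _check_count(v, f"total for {k}") for k, v in self.totals.items()
            }
            for cls, tot in self.totals.items():
                if self.has_distribution(cls) and tot != self._distribution_total(cls):
                    raise ScoreSheetError(
                        f"dose {self.dose_gy} Gy, class {cls}: total {tot} disagrees "
                        f"with the distribution total {self._distribution_total(cls)}"
                    )

    # -- representation queries ------------------------------------------

    def has_distribution(self, aberration_class: str) -> bool:
        cls = resolve_class(aberration_class)
        return self.cells is not None or (
            self.distributions is not None and cls in self.distributions
        )

    def distribution(self, aberration_class: str) -> dict[int, int]:
        """count -> number of cells, derived from cells when available."""
        cls = resolve_class(aberration_class)
        if self.cells is not None:
            return aggregate_distribution(self.cells, cls)
        if self.distributions is not None and cls in self.distributions:
            return dict(self.distributions[cls])
        raise DistributionUnavailableError(
            f"dose {self.dose_gy} Gy: no per-cell distribution for class {cls!r} "
            "(only totals were recorded)"
        )

    def _distribution_total(self, cls: str) -> int:
        return sum(k * n for k, n in self.distribution(cls).items())

    def total(self, aberration_class: str) -> int:
        """Total aberration count X for one class at this dose."""
        cls = resolve_class(aberration_class)
        if self.has_distribution(cls):
            return self._distribution_total(cls)
        if self.totals is not None and cls in self.totals:
            return self.totals[cls]
        raise ScoreSheetError(
            f"dose {self.dose_gy} Gy: no data recorded for class {cls!r}"
        )


@dataclass
class ScoreSheet:
    """A set of dose points sharing sample metadata."""

    points: list[DosePoint] = field(default_factory=list)
    sample_id: str = "sample"
    preparation: str = "G2_PCC"
    culture_hours: float = 48.0
    donor: str = "donor1"

    def __post_init__(self) -> None:
        doses = [p.dose_gy for p in self.points]
        if len(set(doses)) != len(doses):
            raise ScoreSheetError(f"duplicate dose values in sheet {self.sample_id!r}: {doses}")
        self.points = sorted(self.points, key=lambda p: p.dose_gy)

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def point_at(self, dose_gy: float) -> DosePoint:
        for p in self.points:
            if p.dose_gy == dose_gy:
                return p
        raise KeyError(f"no dose point at {dose_gy} Gy")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

PER_CELL_HEADER = [
    "sample_id",
    "preparation",
    "culture_hours",
    "donor",
    "dose_gy",
    "cell_id",
    *ABERRATION_CLASSES,
]

DISTRIBUTION_HEADER = ["dose_gy", "cells_scored", "aberration_class", "count", "n_cells"]


def _parse_int(text: str, what: str, row: int) -> int:
    try:
        value = int(text)
    except ValueError:
        raise ParseError(f"{what} must be an integer, got {text!r}", row)
    if value < 0:
        raise ParseError(f"{what} must be >= 0, got {value}", row)
    return value


def _read_per_cell(reader: csv.DictReader) -> ScoreSheet:
    meta: dict[str, object] | None = None
    by_dose: dict[float, list[CellRecord]] = {}
    for i, row in enumerate(reader, start=2):
        try:
            dose = float(row["dose_gy"])
        except (TypeError, ValueError, KeyError):
            raise ParseError(f"bad dose_gy value {row.get('dose_gy')!r}", i)
        counts = {c: _parse_int(row[c], c, i) for c in ABERRATION_CLASSES}
        cell = CellRecord(cell_id=row["cell_id"], **counts)
        row_meta = {
            "sample_id": row["sample_id"],
            "preparation": row["preparation"],
            "culture_hours": float(row["culture_hours"]),
            "donor": row["donor"],
        }
        if meta is None:
            meta = row_meta
        elif row_meta != meta:
            raise ParseError("sample metadata changes mid-sheet", i)
        by_dose.setdefault(dose, []).append(cell)
    if meta is None:
        raise ParseError("empty score sheet (no data rows)")
    points = [
        DosePoint(
            dose_gy=d,
            n_cells=len(cells),
            cells=cells,
            preparation=str(meta["preparation"]),
            culture_hours=float(meta["culture_hours"]),  # type: ignore[arg-type]
            donor=str(meta["donor"]),
        )
        for d, cells in by_dose.items()
    ]
    return ScoreSheet(
        points=points,
        sample_id=str(meta["sample_id"]),
        preparation=str(meta["preparation"]),
        culture_hours=float(meta["culture_hours"]),  # type: ignore[arg-type]
        donor=str(meta["donor"]),
    )


def _read_distribution(
    reader: csv.DictReader,
    preparation: str,
    culture_hours: float,
    donor: str,
    sample_id: str,
) -> ScoreSheet:
    by_dose: dict[float, dict[str, dict[int, int]]] = {}
    cells_scored: dict[float, int] = {}
    for i, row in enumerate(reader, start=2):
        try:
            dose = float(row["dose_gy"])
        except (TypeError, ValueError, KeyError):
            raise ParseError(f"bad dose_gy value {row.get('dose_gy')!r}", i)
        n_scored = _parse_int(row["cells_scored"], "cells_scored", i)
        if cells_scored.setdefault(dose, n_scored) != n_scored:
            raise ParseError(
                f"cells_scored changes within dose {dose} Gy "
                f"({cells_scored[dose]} vs {n_scored})",
                i,
            )
        try:
            cls = resolve_class(row["aberration_class"])
        except ScoreSheetError as exc:
            raise ParseError(str(exc), i)
        k = _parse_int(row["count"], "count", i)
        n = _parse_int(row["n_cells"], "n_cells", i)
        dist = by_dose.setdefault(dose, {}).setdefault(cls, {})
        if k in dist:
            raise ParseError(f"duplicate count {k} for class {cls} at {dose} Gy", i)
        dist[k] = n
    if not by_dose:
        raise ParseError("empty score sheet (no data rows)")
    points = []
    for dose, dists in by_dose.items():
        points.append(
            DosePoint(
                dose_gy=dose,
                n_cells=cells_scored[dose],
                distributions=dists,
                preparation=preparation,
                culture_hours=culture_hours,
                donor=donor,
            )
        )
    return ScoreSheet(
        points=points,
        sample_id=sample_id,
        preparation=preparation,
        culture_hours=culture_hours,
        donor=donor,
    )


def read_score_sheet(
    path: str | Path | io.TextIOBase,
    format: str = "per_cell_csv",
    *,
    preparation: str = "G2_PCC",
    culture_hours: float = 48.0,
    donor: str = "donor1",
    sample_id: str | None = None,
) -> ScoreSheet:
    """Read a score sheet from one of the two CSV dialects.

    The distribution dialect carries no sample metadata in the file;
    supply it through the keyword arguments.
    """
    own = False
    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path, "r", newline="", encoding="utf-8")
        own = True
        default_id = Path(path).stem
    else:
        handle = path
        default_id = "sample"
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ParseError("empty file (no header)")
        if format == "per_cell_csv":
            if reader.fieldnames != PER_CELL_HEADER:
                raise ParseError(
                    f"per_cell_csv header mismatch: got {reader.fieldnames}"
                )
            return _read_per_cell(reader)
        if format == "distribution_csv":
            if reader.fieldnames != DISTRIBUTION_HEADER:
                raise ParseError(
                    f"distribution_csv header mismatch: got {reader.fieldnames}"
                )
            return _read_distribution(
                reader, preparation, culture_hours, donor, sample_id or default_id
            )
        raise ScoreSheetError(f"unknown format {format!r}")
    finally:
        if own:
            handle.close()


def sniff_format(path: str | Path) -> str:
    """Guess the dialect of a score-sheet CSV from its header line."""
    with open(path, "r", newline="", encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
    if header == PER_CELL_HEADER:
        return "per_cell_csv"
    if header == DISTRIBUTION_HEADER:
        return "distribution_csv"
    raise ParseError(f"unrecognised score-sheet header: {header}")


def write_score_sheet(
    sheet: ScoreSheet,
    path: str | Path | io.TextIOBase,
    format: str = "per_cell_csv",
    *,
    classes: Sequence[str] | None = None,
) -> None:
    """Write a score sheet in one of the two CSV dialects.

    ``per_cell_csv`` requires per-cell records.  ``distribution_csv`` writes
    one block per dose for every class with an available distribution (or
    the subset in ``classes``).
    """
    own = False
    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path, "w", newline="", encoding="utf-8")
        own = True
    else:
        handle = path
    try:
        writer = csv.writer(handle)
        if format == "per_cell_csv":
            writer.writerow(PER_CELL_HEADER)
            for point in sheet:
                if point.cells is None:
                    raise ScoreSheetError(
                        f"dose {point.dose_gy} Gy has no per-cell records; "
                        "cannot write per_cell_csv"
                    )
                for cell in point.cells:
                    writer.writerow(
                        [
                            sheet.sample_id,
                            point.preparation,
                            _fmt_num(point.culture_hours),
                            point.donor,
                            _fmt_num(point.dose_gy),
                            cell.cell_id,
                            *(getattr(cell, c) for c in ABERRATION_CLASSES),
                        ]
                    )
        elif format == "distribution_csv":
            writer.writerow(DISTRIBUTION_HEADER)
            wanted = [resolve_class(c) for c in classes] if classes else list(ABERRATION_CLASSES)
            for point in sheet:
                for cls in wanted:
                    if not point.has_distribution(cls):
                        continue
                    for k, n in sorted(point.distribution(cls).items()):
                        writer.writerow(
                            [_fmt_num(point.dose_gy), point.n_cells, cls, k, n]
                        )
        else:
            raise ScoreSheetError(f"unknown format {format!r}")
    finally:
        if own:
            handle.close()


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))
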