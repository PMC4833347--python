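"""Record schemas and CSV input/output for the queen-morphometry pipeline.

Two raw tables drive everything downstream: a morphometry table (one row
per queen; linear measurements in mm, dry masses in mg, wing dimensions)
and a tethered-flight table (one row per flight bout, in seconds).  Both
are plain comma-separated files with a mandatory snake_case header, "."
decimal separator and empty cells for missing values.  Result tables are
written back as CSV with ``#``-prefixed provenance comment lines.

Units are fixed: mm, mg, s, mm^2.  No unit auto-detection is attempted.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("foundorfly")

SPECIES = ("geminata", "invicta")
CASTES = ("claustral", "parasitic")

#: Column order of the morphometry table; also the field order of
#: :class:`QueenMorphRecord`.
MORPH_COLUMNS = [
    "queen_id",
    "species",
    "caste",
    "colony_id",
    "head_width",
    "abdomen_length",
    "abdomen_height",
    "abdomen_mass",
    "thorax_mass",
    "wing_mass",
    "body_mass",
    "forewing_length",
    "total_wing_area",
]

_MORPH_NUMERIC = MORPH_COLUMNS[4:]

FLIGHT_COLUMNS = ["queen_id", "duration_s", "temperature_C", "humidity_pct"]

#: tolerance for the mass-additivity invariant (component masses were
#: weighed to 0.001 mg, so allow that much slack per component)
_MASS_TOL = 5e-3


class SchemaError(ValueError):
    """A table is missing a mandatory column or has a malformed header."""


class ParseError(ValueError):
    """A cell could not be parsed as the declared type."""


class RecordValidationError(ValueError):
    """A row violates a record invariant."""


class ReferenceError_(KeyError):
    """A flight row references a queen absent from the morphometry table."""


@dataclass(frozen=True)
class QueenMorphRecord:
    """One measured queen: identity, caste labels and dry morphometry.

    Linear measurements are in mm, masses in mg (dry), areas in mm^2.
    Optional numeric fields may be ``None``; operations that need them
    declare so and skip records lacking them.
    """

    queen_id: str
    species: str
    caste: str
    colony_id: str
    head_width: float | None = None
    abdomen_length: float | None = None
    abdomen_height: float | None = None
    abdomen_mass: float | None = None
    thorax_mass: float | None = None
    wing_mass: float | None = None
    body_mass: float | None = None
    forewing_length: float | None = None
    total_wing_area: float | None = None

    def problems(self) -> list[str]:
        """Return all invariant violations (empty list when valid)."""
        out: list[str] = []
        if not self.queen_id:
            out.append("queen_id is empty")
        if self.species not in SPECIES:
            out.append(f"species {self.species!r} not in {SPECIES}")
        if self.caste not in CASTES:
            out.append(f"caste {self.caste!r} not in {CASTES}")
        for name in _MORPH_NUMERIC:
            v = getattr(self, name)
            if v is not None and not v > 0:
                out.append(f"{name}={v} must be strictly positive")
        al, ah = self.abdomen_length, self.abdomen_height
        if al is not None and ah is not None and ah > al:
            out.append(
                f"abdomen_height {ah} exceeds abdomen_length {al} "
                "(length is the major axis)"
            )
        parts = (self.abdomen_mass, self.thorax_mass, self.wing_mass)
        if self.body_mass is not None and all(p is not None for p in parts):
            total = sum(p for p in parts if p is not None)
            if total > self.body_mass + _MASS_TOL:
                out.append(
                    f"component masses sum to {total:.4f} mg, exceeding "
                    f"body_mass {self.body_mass:.4f} mg"
                )
        return out

    def validate(self) -> "QueenMorphRecord":
        probs = self.problems()
        if probs:
            raise RecordValidationError(
                f"queen {self.queen_id!r}: " + "; ".join(probs)
            )
        return self


@dataclass(frozen=True)
class FlightRecord:
    """Tethered-flight bouts for one queen plus her post-flight morphometry."""

    queen_id: str
    colony_id: str
    bout_durations: tuple[float, ...]
    morphometry: QueenMorphRecord | None = None
    temperature_C: float | None = None
    humidity_pct: float | None = None

    MAX_BOUTS = 6

    def problems(self) -> list[str]:
        out: list[str] = []
        if not 1 <= len(self.bout_durations) <= self.MAX_BOUTS:
            out.append(
                f"{len(self.bout_durations)} bouts; must be between 1 and "
                f"{self.MAX_BOUTS}"
            )
        for i, d in enumerate(self.bout_durations):
            if not d > 0:
                out.append(f"bout {i} duration {d} s must be > 0")
        return out

    def validate(self) -> "FlightRecord":
        probs = self.problems()
        if probs:
            raise RecordValidationError(
                f"queen {self.queen_id!r}: " + "; ".join(probs)
            )
        return self


def _parse_float(cell, column: str, row: int) -> float | None:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return None
    if isinstance(cell, str) and cell.strip() == "":
        return None
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row}: non-numeric value {cell!r} in column {column!r}"
        ) from None


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_morphometry_table(path, strict: bool = True) -> list[QueenMorphRecord]:
    """Read and validate a queen morphometry CSV.

    In strict mode any invariant violation raises; otherwise offending
    rows are skipped with one logged warning each, so every input row is
    either accepted or produces exactly one diagnostic.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    _require_columns(df, MORPH_COLUMNS, path)
    records: list[QueenMorphRecord] = []
    rejected = 0
    for i, row in enumerate(df.itertuples(index=False)):
        kwargs = {
            "queen_id": getattr(row, "queen_id").strip(),
            "species": getattr(row, "species").strip(),
            "caste": getattr(row, "caste").strip(),
            "colony_id": getattr(row, "colony_id").strip(),
        }
        try:
            for col in _MORPH_NUMERIC:
                kwargs[col] = _parse_float(getattr(row, col), col, i)
            rec = QueenMorphRecord(**kwargs)
            probs = rec.problems()
            if probs:
                raise RecordValidationError(
                    f"queen {rec.queen_id!r}: " + "; ".join(probs)
                )
        except ParseError:
            raise
        except RecordValidationError as exc:
            if strict:
                raise
            rejected += 1
            logger.warning("%s row %d rejected: %s", path.name, i, exc)
            continue
        records.append(rec)
    logger.info(
        "%s: accepted %d rows, rejected %d", path.name, len(records), rejected
    )
    return records


def write_morphometry_table(
    records: Sequence[QueenMorphRecord], path, precision: int = 6
) -> None:
    """Write queen records to CSV in the canonical column order."""
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in MORPH_COLUMNS} for r in records],
        columns=MORPH_COLUMNS,
    )
    write_results_table(df, path, precision=precision)


def read_flight_table(
    path, morph: Sequence[QueenMorphRecord], strict: bool = True
) -> list[FlightRecord]:
    """Read per-bout flight durations and group them per queen.

    Bouts are grouped in file order; every ``queen_id`` must resolve to a
    morphometry record (its colony and post-flight morphometry are taken
    from there).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    _require_columns(df, ["queen_id", "duration_s"], path)
    by_id = {r.queen_id: r for r in morph}
    bouts: dict[str, list[float]] = {}
    env: dict[str, dict[str, float | None]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        qid = getattr(row, "queen_id").strip()
        if qid not in by_id:
            raise ReferenceError_(
                f"{path.name} row {i}: queen_id {qid!r} not found in "
                "morphometry table"
            )
        d = _parse_float(getattr(row, "duration_s"), "duration_s", i)
        if d is None or d <= 0:
            msg = f"{path.name} row {i}: bout duration {d} s must be > 0"
            if strict:
                raise RecordValidationError(msg)
            logger.warning("%s", msg)
            continue
        bouts.setdefault(qid, []).append(d)
        if qid not in env:
            env[qid] = {
                "temperature_C": _parse_float(
                    getattr(row, "temperature_C", None), "temperature_C", i
                ),
                "humidity_pct": _parse_float(
                    getattr(row, "humidity_pct", None), "humidity_pct", i
                ),
            }
    out = []
    for qid, durations in bouts.items():
        if len(durations) > FlightRecord.MAX_BOUTS:
            raise RecordValidationError(
                f"queen {qid!r} has {len(durations)} bouts "
                f"(maximum {FlightRecord.MAX_BOUTS})"
            )
        rec = FlightRecord(
            queen_id=qid,
            colony_id=by_id[qid].colony_id,
            bout_durations=tuple(durations),
            morphometry=by_id[qid],
            **env[qid],
        ).validate()
        out.append(rec)
    return out


def write_flight_table(records: Sequence[FlightRecord], path, precision: int = 6) -> None:
    rows = []
    for r in records:
        for d in r.bout_durations:
            rows.append(
                {
                    "queen_id": r.queen_id,
                    "duration_s": d,
                    "temperature_C": r.temperature_C,
                    "humidity_pct": r.humidity_pct,
                }
            )
    df = pd.DataFrame(rows, columns=FLIGHT_COLUMNS)
    write_results_table(df, path, precision=precision)


def write_results_table(
    table: pd.DataFrame,
    path,
    precision: int = 6,
    provenance: dict | None = None,
) -> None:
    """Write a result table as UTF-8 CSV with deterministic formatting.

    Floats are serialized with ``precision`` significant digits, so
    write -> read -> write is byte-stable.  ``provenance`` key/value pairs
    (pipeline stage, config digest, seed, ...) become ``#`` comment lines
    above the header; no wall-clock timestamp is added, keeping outputs
    reproducible under a fixed seed.
    """
    if len(set(table.columns)) != len(table.columns):
        raise SchemaError("result table has duplicate column names")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, index=False, float_format=f"%.{precision}g")


def read_results_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_results_table` (comments dropped)."""
    return pd.read_csv(path, comment="#")


def records_to_frame(records: Sequence[QueenMorphRecord]) -> pd.DataFrame:
    """Tabulate queen records (canonical column order)."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=MORPH_COLUMNS
    )
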