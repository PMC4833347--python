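"""Flight-morphology indices for ant queens.

Five scalar indices summarize how a queen's build constrains her flight,
plus the abdomen volume they rest on:

* flight muscle ratio (FMR) — thorax dry mass / total dry body mass; the
  thorax (mesosoma) mass is the standard surrogate for flight muscle.
* wing loading — body mass / combined area of all four wings (mg/mm^2).
* abdomen volume — prolate spheroid from abdomen length and height,
  V = (pi/6) * L * H^2 with L, H read as full diameters.  The semi-axis
  reading (4pi/3) * L * H^2 would inflate volume 8-fold; the diameter
  convention is the one consistent with measured maximum length/height.
* abdomen drag reference area — V^(2/3) (mm^2), the volumetric reference
  area proportional to aerodynamic drag.
* aspect ratio — 4 * forewing length^2 / total wing area (wing
  narrowness, dimensionless).
* wing mass density — total wing mass / total wing area (mg/mm^2).

Indices are always computed per queen; group summaries are taken over
per-queen indices, never from ratios of group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import QueenMorphRecord


class MorphometryError(ValueError):
    """Inputs violate a formula precondition."""


@dataclass(frozen=True)
class MorphometricProfile:
    """Derived flight indices for one queen."""

    queen_id: str
    fmr: float
    wing_loading: float
    abdomen_volume: float
    drag_area: float
    aspect_ratio: float
    wing_mass_density: float


PROFILE_COLUMNS = [
    "queen_id",
    "fmr",
    "wing_loading",
    "abdomen_volume",
    "drag_area",
    "aspect_ratio",
    "wing_mass_density",
]

#: record fields a full profile needs
REQUIRED_FIELDS = (
    "thorax_mass",
    "body_mass",
    "total_wing_area",
    "wing_mass",
    "forewing_length",
    "abdomen_length",
    "abdomen_height",
)


def flight_muscle_ratio(thorax_mass: float, body_mass: float) -> float:
    """Thorax dry mass over total dry body mass, in (0, 1)."""
    if not 0 < thorax_mass < body_mass:
        raise MorphometryError(
            f"need 0 < thorax_mass < body_mass, got {thorax_mass} / {body_mass}"
        )
    return thorax_mass / body_mass


def wing_loading(body_mass: float, total_wing_area: float) -> float:
    """Body mass per unit of total wing area (mg/mm^2)."""
    if body_mass <= 0 or total_wing_area <= 0:
        raise MorphometryError("body_mass and total_wing_area must be > 0")
    return body_mass / total_wing_area


def abdomen_volume(length: float, height: float) -> float:
    """Prolate-spheroid volume (mm^3) from full length and height diameters."""
    if not length >= height > 0:
        raise MorphometryError(
            f"need length >= height > 0, got L={length}, H={height}"
        )
    return math.pi / 6.0 * length * height**2


def drag_reference_area(volume: float) -> float:
    """Volumetric drag reference area: volume^(2/3) (mm^2)."""
    if volume <= 0:
        raise MorphometryError("volume must be > 0")
    return volume ** (2.0 / 3.0)


def aspect_ratio(forewing_length: float, total_wing_area: float) -> float:
    """Wing narrowness: 4 * forewing_length^2 / total_wing_area."""
    if forewing_length <= 0 or total_wing_area <= 0:
        raise MorphometryError("forewing_length and total_wing_area must be > 0")
    return 4.0 * forewing_length**2 / total_wing_area


def wing_mass_density(wing_mass: float, total_wing_area: float) -> float:
    """Wing stiffness proxy: total wing mass / total wing area (mg/mm^2)."""
    if wing_mass <= 0 or total_wing_area <= 0:
        raise MorphometryError("wing_mass and total_wing_area must be > 0")
    return wing_mass / total_wing_area


def profile_queen(record: QueenMorphRecord) -> MorphometricProfile:
    """Compute all indices for one queen record.

    Raises :class:`MorphometryError` naming the queen and the missing
    field if any required measurement is absent.
    """
    missing = [f for f in REQUIRED_FIELDS if getattr(record, f) is None]
    if missing:
        raise MorphometryError(
            f"queen {record.queen_id!r}: missing field(s) {missing}"
        )
    try:
        vol = abdomen_volume(record.abdomen_length, record.abdomen_height)
        return MorphometricProfile(
            queen_id=record.queen_id,
            fmr=flight_muscle_ratio(record.thorax_mass, record.body_mass),
            wing_loading=wing_loading(record.body_mass, record.total_wing_area),
            abdomen_volume=vol,
            drag_area=drag_reference_area(vol),
            aspect_ratio=aspect_ratio(
                record.forewing_length, record.total_wing_area
            ),
            wing_mass_density=wing_mass_density(
                record.wing_mass, record.total_wing_area
            ),
        )
    except MorphometryError as exc:
        raise MorphometryError(f"queen {record.queen_id!r}: {exc}") from exc


def profile_table(records: Sequence[QueenMorphRecord]) -> pd.DataFrame:
    """Profiles for a cohort, joined back to identity and abdomen mass."""
    rows = []
    for rec in records:
        p = profile_queen(rec)
        rows.append(
            {
                "queen_id": p.queen_id,
                "species": rec.species,
                "caste": rec.caste,
                "colony_id": rec.colony_id,
                "abdomen_mass": rec.abdomen_mass,
                "fmr": p.fmr,
                "wing_loading": p.wing_loading,
                "abdomen_volume": p.abdomen_volume,
                "drag_area": p.drag_area,
                "aspect_ratio": p.aspect_ratio,
                "wing_mass_density": p.wing_mass_density,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "queen_id",
            "species",
            "caste",
            "colony_id",
            "abdomen_mass",
            "fmr",
            "wing_loading",
            "abdomen_volume",
            "drag_area",
            "aspect_ratio",
            "wing_mass_density",
        ],
    )
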