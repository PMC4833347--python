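"""Found-or-fly reproduction-dispersal tradeoff model.

Dry abdomen mass a (mg) is converted into dispersal and reproduction
currencies:

* maximum flight duration  D(a) = max(b0 + b1 * a, floor), the upper-
  quartile endurance envelope with a floor for the heaviest queens
  (even fully loaded queens manage short flights of a few hundred
  meters);
* flight speed, either a constant maximum (1.5 m/s), caste-average
  values (0.9 m/s parasitic, 0.6 m/s claustral), or a user-supplied
  mass formula;
* flight range = speed * duration (purely horizontal flight);
* potential colonization area = pi * range^2, in km^2;
* first-generation worker production, by default a two-point linear
  calibration through (2.7 mg -> 10 workers) and (5.3 mg -> 31 workers),
  clamped at zero below its root.  The calibration stands in for an
  unpublished rearing-study formula on live abdomen mass; any monotone
  callable of live mass (live = dry * live_dry_ratio) may be plugged in.

Headline numbers use the printed rounding conventions — duration to the
nearest 100 s, range to the nearest m, area to the nearest km^2 —
because the published contrast ratios are only mutually consistent under
that rounding; unrounded values are always reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd


class TradeoffError(ValueError):
    pass


def _round_to(value: float, step: float) -> float:
    """Round half-up to the nearest multiple of ``step``."""
    return math.floor(value / step + 0.5) * step


# default worker-production calibration points: (dry abdomen mg, workers)
_WORKER_CAL = ((2.7, 10.0), (5.3, 31.0))


@dataclass(frozen=True)
class TradeoffConfig:
    """Constants of the tradeoff model (units in field comments)."""

    endurance_intercept: float = 6742.350  # s
    endurance_slope: float = -1096.915  # s/mg (dry abdomen mass)
    duration_floor: float = 160.0  # s
    live_dry_ratio: float = 2.0  # live mass / dry mass
    speed_mode: str = "constant_max"  # constant_max | caste_average | mass_formula
    speed_max: float = 1.5  # m/s
    speed_parasitic: float = 0.9  # m/s
    speed_claustral: float = 0.6  # m/s
    speed_formula: Callable[[float], float] | None = None  # of live body mass
    worker_model: Callable[[float], float] | None = None  # of live abdomen mass
    rounding: bool = True  # printed-style rounding of headline values

    def __post_init__(self):
        if self.endurance_slope >= 0:
            raise TradeoffError("endurance_slope must be negative")
        if self.duration_floor <= 0:
            raise TradeoffError("duration_floor must be > 0")
        if self.live_dry_ratio <= 0:
            raise TradeoffError("live_dry_ratio must be > 0")
        if min(self.speed_max, self.speed_parasitic, self.speed_claustral) <= 0:
            raise TradeoffError("speeds must be > 0")
        if self.speed_mode not in ("constant_max", "caste_average", "mass_formula"):
            raise TradeoffError(f"unknown speed_mode {self.speed_mode!r}")

    @property
    def floor_crossing_mass(self) -> float:
        """Dry abdomen mass (mg) where the envelope meets the floor;
        durations for heavier queens are extrapolation."""
        return (self.duration_floor - self.endurance_intercept) / self.endurance_slope


@dataclass(frozen=True)
class TradeoffPrediction:
    """Model outputs at one dry abdomen mass (unrounded scale)."""

    abdomen_mass: float  # mg dry
    max_duration: float  # s
    speed: float  # m/s
    flight_range: float  # m
    colonization_area: float  # km^2
    workers: float
    # printed-style rounded companions
    max_duration_rounded: float
    flight_range_rounded: float
    colonization_area_rounded: float


def max_flight_duration(abdomen_mass: float, config: TradeoffConfig | None = None) -> float:
    """Upper-envelope maximum total flight time (s), floored."""
    config = config or TradeoffConfig()
    if abdomen_mass <= 0:
        raise TradeoffError("abdomen_mass must be > 0")
    return max(
        config.endurance_intercept + config.endurance_slope * abdomen_mass,
        config.duration_floor,
    )


def flight_speed(
    caste: str,
    config: TradeoffConfig | None = None,
    body_mass: float | None = None,
) -> float:
    """Flight speed (m/s) under the configured mode."""
    config = config or TradeoffConfig()
    if config.speed_mode == "constant_max":
        return config.speed_max
    if config.speed_mode == "caste_average":
        if caste == "claustral":
            return config.speed_claustral
        if caste == "parasitic":
            return config.speed_parasitic
        raise TradeoffError(f"unknown caste {caste!r}")
    if config.speed_formula is None:
        raise TradeoffError("speed_mode='mass_formula' requires speed_formula")
    if body_mass is None:
        raise TradeoffError("mass_formula mode needs body_mass")
    return float(config.speed_formula(body_mass))


def colonization_area(
    duration: float, speed: float, rounded: bool = False
) -> float:
    """Circular search area (km^2) reachable in a straight-line flight.

    radius = duration * speed (m); area = pi * radius^2 / 1e6 km^2;
    ``rounded=True`` rounds to the nearest integer km^2.
    """
    if duration <= 0 or speed <= 0:
        raise TradeoffError("duration and speed must be > 0")
    radius_km = duration * speed / 1000.0
    area = math.pi * radius_km**2
    return _round_to(area, 1.0) if rounded else area


def worker_production(
    abdomen_mass: float, config: TradeoffConfig | None = None
) -> float:
    """First-generation workers from a dry abdomen mass (mg), clamped >= 0."""
    config = config or TradeoffConfig()
    if abdomen_mass <= 0:
        raise TradeoffError("abdomen_mass must be > 0")
    if config.worker_model is not None:
        w = float(config.worker_model(abdomen_mass * config.live_dry_ratio))
    else:
        (a1, w1), (a2, w2) = _WORKER_CAL
        slope = (w2 - w1) / (a2 - a1)
        w = w1 + slope * (abdomen_mass - a1)
    return max(w, 0.0)


def predict(
    abdomen_mass: float,
    config: TradeoffConfig | None = None,
    caste: str = "claustral",
    body_mass: float | None = None,
) -> TradeoffPrediction:
    """All model outputs at one dry abdomen mass.

    Ranges and areas are derived from the *rounded* duration when
    ``config.rounding`` is on (the printed convention) and from the raw
    duration otherwise; unrounded companions always use the raw values.
    """
    config = config or TradeoffConfig()
    dur = max_flight_duration(abdomen_mass, config)
    dur_r = _round_to(dur, 100.0)
    speed = flight_speed(caste, config, body_mass)
    headline_dur = dur_r if config.rounding else dur
    rng = dur * speed
    rng_head = headline_dur * speed
    return TradeoffPrediction(
        abdomen_mass=abdomen_mass,
        max_duration=dur,
        speed=speed,
        flight_range=rng,
        colonization_area=colonization_area(dur, speed, rounded=False),
        workers=worker_production(abdomen_mass, config),
        max_duration_rounded=dur_r,
        flight_range_rounded=_round_to(rng_head, 1.0),
        colonization_area_rounded=colonization_area(
            headline_dur, speed, rounded=True
        ),
    )


def tradeoff_curve(
    mass_grid: Sequence[float],
    config: TradeoffConfig | None = None,
    caste: str = "claustral",
) -> pd.DataFrame:
    """Evaluate the model on an ascending grid of dry abdomen masses."""
    grid = list(mass_grid)
    if not grid:
        raise TradeoffError("empty mass grid")
    if any(m <= 0 for m in grid):
        raise TradeoffError("grid masses must be > 0")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise TradeoffError("grid must be ascending")
    rows = [predict(m, config, caste).__dict__ for m in grid]
    return pd.DataFrame(rows)


def caste_contrast(
    claustral_mass: float = 5.3,
    parasitic_mass: float = 2.7,
    config: TradeoffConfig | None = None,
) -> pd.DataFrame:
    """Claustral vs parasitic fold-differences under both speed modes.

    One row per speed mode; fold columns are parasitic/claustral for the
    dispersal currencies (parasites fly farther) and claustral/parasitic
    for workers.  ``*_fold_rounded`` ratios are taken between the
    printed-style rounded values, ``*_fold`` between unrounded ones.
    """
    config = config or TradeoffConfig()
    rows = []
    for mode in ("constant_max", "caste_average"):
        cfg = TradeoffConfig(
            **{
                **{
                    f: getattr(config, f)
                    for f in config.__dataclass_fields__
                },
                "speed_mode": mode,
            }
        )
        cla = predict(claustral_mass, cfg, caste="claustral")
        par = predict(parasitic_mass, cfg, caste="parasitic")
        rows.append(
            {
                "speed_mode": mode,
                "claustral_duration_s": cla.max_duration_rounded,
                "parasitic_duration_s": par.max_duration_rounded,
                "claustral_range_m": cla.flight_range_rounded,
                "parasitic_range_m": par.flight_range_rounded,
                "claustral_area_km2": cla.colonization_area_rounded,
                "parasitic_area_km2": par.colonization_area_rounded,
                "claustral_workers": cla.workers,
                "parasitic_workers": par.workers,
                "duration_fold": par.max_duration / cla.max_duration,
                "duration_fold_rounded": par.max_duration_rounded
                / cla.max_duration_rounded,
                "range_fold": par.flight_range / cla.flight_range,
                "range_fold_rounded": par.flight_range_rounded
                / cla.flight_range_rounded,
                "area_fold": par.colonization_area / cla.colonization_area,
                "area_fold_rounded": par.colonization_area_rounded
                / cla.colonization_area_rounded,
                "worker_fold": cla.workers / par.workers
                if par.workers > 0
                else math.inf,
            }
        )
    return pd.DataFrame(rows)
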