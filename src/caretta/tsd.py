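"""Temperature-dependent reproductive parameters.

Loggerhead sea turtles have temperature-dependent sex determination (TSD):
the sand temperature during the middle third of incubation sets the offspring
sex ratio, and extreme heat additionally depresses emergence success.  This
module holds the temperature grid of reproductive parameters — incubation
duration ``Id`` (days), percent female offspring ``Of`` and emergence success
``Es`` (both percentages) — and interpolates them at arbitrary incubation
temperatures for use by the colonisation model.

Internally everything is converted once to proportions in [0, 1]; the
percentage unit appears only at file boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TemperatureGrid",
    "TSDParams",
    "default_grid",
    "params_at",
    "sex_ratio_from_duration",
]


class GridValidationError(ValueError):
    """Raised for an empty or non-monotone temperature grid."""


@dataclass(frozen=True)
class TSDParams:
    """Reproductive parameters at one incubation temperature.

    of
        Proportion of female offspring, in [0, 1].
    es
        Proportion of eggs producing emerged hatchlings, in [0, 1].
    id_days
        Incubation duration in days (> 0).
    """

    of: float
    es: float
    id_days: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.of <= 1.0):
            raise ValueError(f"of must be in [0, 1], got {self.of}")
        if not (0.0 <= self.es <= 1.0):
            raise ValueError(f"es must be in [0, 1], got {self.es}")
        if not self.id_days > 0:
            raise ValueError(f"id_days must be positive, got {self.id_days}")


@dataclass(frozen=True)
class TemperatureGrid:
    """Table of (temperature, Id, Of, Es) rows, percentages on the file scale.

    Temperatures must be strictly increasing; percent columns live in
    [0, 100]; incubation durations are strictly positive.
    """

    temperatures: tuple[float, ...]
    incubation_days: tuple[float, ...]
    percent_female: tuple[float, ...]
    emergence_success: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.temperatures)
        if n == 0:
            raise GridValidationError("temperature grid is empty")
        if any(
            len(col) != n
            for col in (self.incubation_days, self.percent_female, self.emergence_success)
        ):
            raise GridValidationError("grid columns have unequal lengths")
        if any(b <= a for a, b in zip(self.temperatures, self.temperatures[1:])):
            raise GridValidationError("grid temperatures must be strictly increasing")
        for name, col, lo, hi in (
            ("percent_female", self.percent_female, 0.0, 100.0),
            ("emergence_success", self.emergence_success, 0.0, 100.0),
        ):
            if any(not (lo <= v <= hi) for v in col):
                raise GridValidationError(f"{name} outside [{lo}, {hi}]")
        if any(d <= 0 for d in self.incubation_days):
            raise GridValidationError("incubation_days must be strictly positive")

    @property
    def tmin(self) -> float:
        return self.temperatures[0]

    @property
    def tmax(self) -> float:
        return self.temperatures[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temperature_c": self.temperatures,
                "incubation_days": self.incubation_days,
                "percent_female": self.percent_female,
                "emergence_success": self.emergence_success,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TemperatureGrid":
        df = df.sort_values("temperature_c")
        return cls(
            temperatures=tuple(float(v) for v in df["temperature_c"]),
            incubation_days=tuple(float(v) for v in df["incubation_days"]),
            percent_female=tuple(float(v) for v in df["percent_female"]),
            emergence_success=tuple(float(v) for v in df["emergence_success"]),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TemperatureGrid":
        """Read a 4-column CSV (comment lines starting with ``#`` ignored)."""
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_grid() -> TemperatureGrid:
    """The packaged six-temperature grid (28–33 °C) used throughout."""
    with resources.as_file(resources.files("caretta") / "data" / "tsd_grid.csv") as p:
        return TemperatureGrid.from_csv(p)


def params_at(grid: TemperatureGrid, temperature: float) -> TSDParams:
    """Interpolate reproductive parameters at an incubation temperature.

    Exact at grid temperatures; piecewise linear between adjacent rows.
    Below the coldest row the sex ratio is forced to all-male (``of = 0``,
    no females are produced below the pivotal temperature) while ``es`` and
    ``id_days`` keep the coldest row's values; queries are accepted down to
    one degree below the grid.  Above the hottest row the hottest row is
    used, with a warning.
    """
    if not math.isfinite(temperature):
        raise ValueError(f"temperature must be finite, got {temperature}")
    if temperature < grid.tmin - 1.0:
        raise ValueError(
            f"temperature {temperature} below supported range "
            f"[{grid.tmin - 1.0}, {grid.tmax}]"
        )
    if temperature < grid.tmin:
        return TSDParams(of=0.0, es=grid.emergence_success[0] / 100.0,
                         id_days=grid.incubation_days[0])
    if temperature > grid.tmax:
        logger.warning(
            "temperature %.2f above grid maximum %.2f; clamping to hottest row",
            temperature, grid.tmax,
        )
        temperature = grid.tmax
    t = np.asarray(grid.temperatures)
    of = float(np.interp(temperature, t, grid.percent_female)) / 100.0
    es = float(np.interp(temperature, t, grid.emergence_success)) / 100.0
    idd = float(np.interp(temperature, t, grid.incubation_days))
    return TSDParams(of=of, es=es, id_days=idd)


def sex_ratio_from_duration(
    id_days: float, pivotal_duration: float = 56.5, slope: float = 1.0
) -> float:
    """Proportion of females from incubation duration, as a logistic curve.

    Incubation duration shortens with temperature, so longer incubations
    mean colder, more male-biased nests.  The curve is
    ``1 / (1 + exp(slope * (id_days - pivotal_duration)))``: 0.5 at the
    pivotal duration, strictly decreasing in ``id_days``.  A single
    configurable curve standing in for the several published
    duration-to-sex-ratio calibrations.
    """
    if not (math.isfinite(id_days) and math.isfinite(pivotal_duration) and math.isfinite(slope)):
        raise ValueError("sex_ratio_from_duration requires finite inputs")
    if id_days <= 0:
        raise ValueError(f"id_days must be positive, got {id_days}")
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    # guard exp overflow for very long durations
    z = slope * (id_days - pivotal_duration)
    if z > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(z))
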