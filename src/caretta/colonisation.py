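"""Deterministic colonisation model for a philopatric nester.

An empty nesting area receives a constant stream of sporadic clutches from
distant populations (propagule pressure rate ``Pr``, clutches/year).  Female
hatchlings born there imprint on the new beach and, if they survive the
``Ma`` years to maturity, return to breed for up to ``Tr + 1`` seasons with
annual adult survival ``Sa``.  The annual recursion tracks

* ``Fc(t) = Pr·En·Es·Of`` — hatchling females from colonisers (constant;
  accidental colonisers lay a single nest each),
* ``Fp(t) = N(t)·En·Es·Of·Cy`` — hatchling females from resident females,
* ``F(t) = Fc(t) + Fp(t)``,
* ``R(t) = Sm·F(t − Ma)`` — new recruits,
* ``N(t) = Σ_{i=t−Tr}^{t} R(i)·Sa^{t−i}`` — reproductively active females,

with all state zero before year 0.  ``Of`` and ``Es`` come from the TSD
grid at the scenario's incubation temperature, so the whole colonisation
outcome is driven by beach temperature and propagule pressure.  The
recursion is linear in ``Pr`` unless a ceiling on ``N`` is set.

Females are continuous (fractional) by default; a seeded stochastic mode
drawing Poisson clutch counts and binomial survival is provided for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tsd import TemperatureGrid, TSDParams, params_at

__all__ = [
    "DemographicParams",
    "Trajectory",
    "simulate",
    "establishment_year",
    "scenario_sweep",
    "long_run_growth_rate",
    "NOT_REACHED",
]

#: sentinel returned by :func:`establishment_year` when the threshold is never met
NOT_REACHED = "not reached"


@dataclass(frozen=True)
class DemographicParams:
    """Parameter set for the annual recursion.

    pr
        Propagule pressure rate: sporadic clutches laid per year by
        accidental colonisers (each lays a single nest).
    en
        Mean eggs per nest (default 112).
    cy
        Mean clutches laid per resident female per year (default 3).
    sm
        Survival proportion hatch → maturity (default 0.005, i.e. 0.5%).
    ma
        Age at maturity in years (default 24, Mediterranean-origin value;
        29 for Atlantic-origin turtles).
    sa
        Annual adult survival proportion (default 0.809).
    tr
        Duration of the reproductive period in years (default 29, midpoint
        of the published 23–35 range); recruits breed in their recruitment
        year and for ``tr`` further years.
    tsd
        Sex ratio / emergence parameters at the scenario temperature.
    ceiling
        Optional hard cap on N (density dependence stand-in); None = none.
    """

    pr: float
    tsd: TSDParams
    en: float = 112.0
    cy: float = 3.0
    sm: float = 0.005
    ma: int = 24
    sa: float = 0.809
    tr: int = 29
    ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.pr < 0:
            raise ValueError(f"pr must be >= 0, got {self.pr}")
        if self.en <= 0:
            raise ValueError(f"en must be > 0, got {self.en}")
        if self.cy < 0:
            raise ValueError(f"cy must be >= 0, got {self.cy}")
        if not (0.0 <= self.sm <= 1.0):
            raise ValueError(f"sm must be in [0, 1], got {self.sm}")
        if not (0.0 <= self.sa <= 1.0):
            raise ValueError(f"sa must be in [0, 1], got {self.sa}")
        if int(self.ma) != self.ma or self.ma < 1:
            raise ValueError(f"ma must be an integer >= 1, got {self.ma}")
        if int(self.tr) != self.tr or self.tr < 0:
            raise ValueError(f"tr must be an integer >= 0, got {self.tr}")
        if self.ceiling is not None and self.ceiling <= 0:
            raise ValueError(f"ceiling must be > 0 if set, got {self.ceiling}")

    def with_tsd(self, tsd: TSDParams) -> "DemographicParams":
        return replace(self, tsd=tsd)


@dataclass(frozen=True)
class Trajectory:
    """Annual series for t = 0..horizon (inclusive arrays, length horizon+1)."""

    fc: np.ndarray  # hatchling females from colonisers
    fp: np.ndarray  # hatchling females from residents
    f: np.ndarray   # total hatchling females
    r: np.ndarray   # recruited females
    n: np.ndarray   # reproductively active females
    params: DemographicParams | None = None

    @property
    def horizon(self) -> int:
        return len(self.n) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(len(self.n)),
                "Fc": self.fc,
                "Fp": self.fp,
                "F": self.f,
                "R": self.r,
                "N": self.n,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write year/Fc/Fp/F/R/N as TSV with a parameter provenance header."""
        path = Path(path)
        with path.open("w") as fh:
            if self.params is not None:
                p = self.params
                fh.write(
                    "# colonisation trajectory: "
                    f"Pr={p.pr} En={p.en} Cy={p.cy} Sm={p.sm} Ma={p.ma} "
                    f"Sa={p.sa} Tr={p.tr} Of={p.tsd.of} Es={p.tsd.es} "
                    f"ceiling={p.ceiling}\n"
                )
            self.to_frame().to_csv(fh, sep="\t", index=False)


def simulate(
    params: DemographicParams,
    horizon: int,
    *,
    stochastic: bool = False,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run the annual recursion for ``horizon`` years (t = 0..horizon).

    Within each year the evaluation order is: recruits R(t) from the female
    production Ma years earlier, then the active population N(t) from the
    recruitment history, then resident production Fp(t), then total
    production F(t).  A ceiling, if set, caps N(t) after the survival sum.

    With ``stochastic=True`` the resident clutch count is Poisson and
    recruitment/adult survival are binomial draws (an extension for
    sensitivity analysis; requires a seeded ``rng``).
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if stochastic and rng is None:
        raise ValueError("stochastic mode requires a seeded numpy Generator")

    p = params
    T = horizon
    fc = np.full(T + 1, p.pr * p.en * p.tsd.es * p.tsd.of)
    fp = np.zeros(T + 1)
    f = np.zeros(T + 1)
    r = np.zeros(T + 1)
    n = np.zeros(T + 1)
    ma, tr = int(p.ma), int(p.tr)
    sa_pow = p.sa ** np.arange(tr + 1)  # survival weights for ages 0..tr since recruitment

    if stochastic:
        fc = rng.poisson(fc).astype(float)

    for t in range(T + 1):
        past_f = f[t - ma] if t - ma >= 0 else 0.0
        if stochastic:
            r[t] = rng.binomial(int(round(past_f)), p.sm) if past_f > 0 else 0.0
        else:
            r[t] = p.sm * past_f
        lo = max(0, t - tr)
        ages = t - np.arange(lo, t + 1)
        n[t] = float(np.dot(r[lo : t + 1], sa_pow[ages]))
        if p.ceiling is not None:
            n[t] = min(n[t], p.ceiling)
        prod = n[t] * p.en * p.tsd.es * p.tsd.of * p.cy
        if stochastic:
            clutches = rng.poisson(n[t] * p.cy)
            prod = clutches * p.en * p.tsd.es * p.tsd.of
        fp[t] = prod
        f[t] = fc[t] + fp[t]

    return Trajectory(fc=fc, fp=fp, f=f, r=r, n=n, params=p)


def establishment_year(traj: Trajectory, threshold: float) -> int | str:
    """First year the active female population reaches ``threshold``.

    Returns :data:`NOT_REACHED` if the trajectory never crosses it.  A
    threshold of ~20 females corresponds to the smallest Mediterranean
    rookeries.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    hits = np.nonzero(traj.n >= threshold)[0]
    return int(hits[0]) if hits.size else NOT_REACHED


def scenario_sweep(
    grid: TemperatureGrid,
    temps: Sequence[float],
    prs: Sequence[float],
    base: DemographicParams,
    horizon: int,
) -> dict[tuple[float, float], Trajectory]:
    """One deterministic trajectory per (temperature, Pr) cell.

    ``Of`` and ``Es`` for each cell come from :func:`caretta.tsd.params_at`
    on ``grid``; all other parameters are taken from ``base``.
    """
    out: dict[tuple[float, float], Trajectory] = {}
    for temp in temps:
        tsd = params_at(grid, temp)
        for pr in prs:
            if pr < 0:
                raise ValueError(f"Pr must be >= 0, got {pr}")
            cell = replace(base, pr=pr, tsd=tsd)
            out[(float(temp), float(pr))] = simulate(cell, horizon)
    return out


def sweep_to_frame(sweep: dict[tuple[float, float], Trajectory]) -> pd.DataFrame:
    """Long-format table (temperature, Pr, year, N) of a sweep result."""
    parts = []
    for (temp, pr), traj in sweep.items():
        parts.append(
            pd.DataFrame(
                {
                    "temperature_c": temp,
                    "pr": pr,
                    "year": np.arange(len(traj.n)),
                    "N": traj.n,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


class UndefinedGrowthRate(ValueError):
    """The trajectory is zero somewhere in the requested window."""


def long_run_growth_rate(traj: Trajectory, window: int = 50) -> float:
    """Geometric mean of N(t+1)/N(t) over the final ``window`` years.

    For an established, unbounded population this approaches the dominant
    eigenvalue of the linear recursion.  Raises
    :class:`UndefinedGrowthRate` when N vanishes inside the window.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > traj.horizon:
        raise ValueError("window longer than trajectory")
    tail = traj.n[-(window + 1):]
    if np.any(tail <= 0):
        raise UndefinedGrowthRate("population is zero within the window")
    ratios = tail[1:] / tail[:-1]
    return float(np.exp(np.mean(np.log(ratios))))
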