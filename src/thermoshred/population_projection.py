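"""Population-level shredding capacity across temperature.

For a hypothetical population of 100 animals, shredding capacity at a
temperature is the exact product

    capacity (g leaf / 72 h) =
        mass-specific rate over 72 h  x  mean body mass (g)
        x  survival fraction at 72 h  x  population size,

with the rate back-transformed from an Arrhenius fit.  The native species'
steeper mortality can cancel its rate gain, flattening capacity against
temperature, while a heat-tolerant invader keeps rising; the Pearson
correlation of capacity with temperature quantifies that contrast, and the
species capacity ratio expresses how much more one species processes at a
given temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mte_arrhenius import ArrheniusFit

__all__ = [
    "PopulationProjection",
    "project_capacity",
    "projections_to_frame",
    "CapacityTrend",
    "capacity_trend",
    "species_capacity_ratio",
]

#: mean wet body masses (g) used for the default projections
DEFAULT_MEAN_MASS_G = {"G. pulex": 0.0305, "D. villosus": 0.0682}


@dataclass
class PopulationProjection:
    species: str
    temp_c: float
    mass_specific_rate_72h: float  # g leaf / g body / 72 h
    mean_mass_g: float
    survival: float
    n_population: int
    capacity_g: float  # g leaf per 72 h for the whole population


def project_capacity(
    fit: ArrheniusFit,
    survival: Mapping[float, float] | Callable[[float], float],
    mean_mass_g: float,
    temps_c: Sequence[float],
    n_population: int = 100,
    trial_days: float = 3.0,
) -> list[PopulationProjection]:
    """Capacity rows for one species over a set of temperatures.

    ``fit`` supplies the per-day mass-specific rate ``exp(intercept +
    E_a * x(T))``, scaled to the 72 h window by ``trial_days``;
    ``survival`` maps temperature to the fraction alive at 72 h (a mapping
    or a callable).  Raises when a survival value leaves [0, 1].
    """
    rows = []
    for t in temps_c:
        s = survival(t) if callable(survival) else survival[t]
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"survival {s} at {t} degC outside [0, 1]")
        rate_72h = float(fit.rate_at(t)) * trial_days
        rows.append(
            PopulationProjection(
                species=fit.species,
                temp_c=float(t),
                mass_specific_rate_72h=rate_72h,
                mean_mass_g=float(mean_mass_g),
                survival=float(s),
                n_population=int(n_population),
                capacity_g=rate_72h * mean_mass_g * s * n_population,
            )
        )
    return rows


def projections_to_frame(projections: Sequence[PopulationProjection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": p.species,
                "temp_c": p.temp_c,
                "mass_specific_rate_72h": p.mass_specific_rate_72h,
                "mean_mass_g": p.mean_mass_g,
                "survival": p.survival,
                "n_population": p.n_population,
                "capacity_g": p.capacity_g,
            }
            for p in projections
        ]
    )


class CapacityTrend(NamedTuple):
    r: float
    p: float
    n: int
    constant: bool  # capacity had no variance; r reported as 0


def capacity_trend(projections: Sequence[PopulationProjection]) -> CapacityTrend:
    """Pearson correlation of capacity with temperature.

    Two-sided p from ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n - 2 df.  A
    constant capacity profile has no defined correlation and is reported
    as r = 0 with the ``constant`` flag set.
    """
    temps = np.array([p.temp_c for p in projections], dtype=float)
    caps = np.array([p.capacity_g for p in projections], dtype=float)
    if temps.size < 3:
        raise ValueError("need >= 3 temperatures for a correlation")
    cap_scale = np.max(np.abs(caps)) if caps.size else 0.0
    if np.ptp(caps) <= 1e-12 * cap_scale or np.ptp(temps) == 0:
        return CapacityTrend(r=0.0, p=float("nan"), n=temps.size, constant=True)
    r, p = stats.pearsonr(temps, caps)
    return CapacityTrend(r=float(r), p=float(p), n=temps.size, constant=False)


def species_capacity_ratio(
    projections: Sequence[PopulationProjection],
    temp_c: float,
    species_a: str = "G. pulex",
    species_b: str = "D. villosus",
) -> float:
    """Percent by which species A out-shreds species B at a temperature.

    ``100 * (capacity_A - capacity_B) / capacity_B``; 200% means A
    processes three times as much leaf as B.
    """

    def _cap(species: str) -> float:
        for p in projections:
            if p.species == species and abs(p.temp_c - temp_c) < 1e-9:
                return p.capacity_g
        raise ValueError(f"no projection for {species} at {temp_c} degC")

    cap_a, cap_b = _cap(species_a), _cap(species_b)
    if cap_b == 0:
        raise ZeroDivisionError(f"zero capacity for {species_b} at {temp_c} degC")
    return 100.0 * (cap_a - cap_b) / cap_b
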