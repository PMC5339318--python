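"""Metabolic-theory (Boltzmann-Arrhenius) analysis of shredding rates.

Water temperature is standardised as ``x = 1/(k T_ref) - 1/(k T)`` with
``k = 8.62e-5 eV/K`` and ``T_ref = 288.15 K`` (15 degC), so that higher
``x`` means warmer water and ``x(15 degC) = 0``.  Regressing the natural
log of the per-temperature mean shredding rate on ``x`` gives an intercept
(ln rate at 15 degC) and a slope that estimates the activation energy of
the consumer-resource interaction in electron-volts.  Metabolic theory
predicts slopes around 0.60-0.70 eV.

Fits are computed one point per experimental temperature (the mean rate is
taken first, then logged), which is also what gives the species-comparison
ANCOVA its 12 denominator degrees of freedom on a 2 x 8 temperature design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "K_BOLTZMANN_EV",
    "T_REF_C",
    "boltzmann_x",
    "ArrheniusFit",
    "arrhenius_fit",
    "arrhenius_table",
    "fits_to_frame",
    "frame_to_fits",
    "mte_band_check",
    "AncovaResult",
    "species_ancova",
    "MTE_BAND_EV",
]

#: Boltzmann constant in eV per Kelvin (printed precision used throughout)
K_BOLTZMANN_EV = 8.62e-5

#: reference temperature for the standardisation, degC
T_REF_C = 15.0

#: predicted activation-energy band for consumer-resource interactions (eV)
MTE_BAND_EV = (0.60, 0.70)

_ABS_ZERO_C = -273.15


def boltzmann_x(temp_c, ref_c: float = T_REF_C):
    """Boltzmann-standardised temperature ``1/(k T_ref) - 1/(k T)`` (1/eV).

    Strictly increasing in ``temp_c`` and exactly zero at the reference
    temperature.  Accepts scalars or arrays.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= _ABS_ZERO_C) or ref_c <= _ABS_ZERO_C:
        raise ValueError("temperature at or below absolute zero")
    t_k = t + 273.15
    ref_k = ref_c + 273.15
    x = 1.0 / (K_BOLTZMANN_EV * ref_k) - 1.0 / (K_BOLTZMANN_EV * t_k)
    return float(x) if np.isscalar(temp_c) else x


@dataclass
class ArrheniusFit:
    """ln(mean rate) ~ intercept + slope * x; slope is the activation energy."""

    species: str
    dataset: str  # "size-matched" | "all-data"
    intercept: float
    intercept_ci: tuple[float, float]
    slope_ev: float
    slope_ci: tuple[float, float]
    r_squared: float
    p_value: float
    n_points: int

    def rate_at(self, temp_c, ref_c: float = T_REF_C):
        """Back-transformed mean rate at a temperature (same units as input)."""
        return np.exp(self.intercept + self.slope_ev * boltzmann_x(temp_c, ref_c))


def arrhenius_fit(
    temps_c: Sequence[float],
    mean_rates: Sequence[float],
    species: str = "",
    dataset: str = "",
    ref_c: float = T_REF_C,
) -> ArrheniusFit:
    """OLS of ln(per-temperature mean rate) on Boltzmann-standardised temperature.

    Non-positive mean rates (ln undefined) are dropped with a warning; at
    least three usable temperatures are required so that the t-based 95%
    confidence intervals (n - 2 df) exist.
    """
    temps = np.asarray(temps_c, dtype=float)
    rates = np.asarray(mean_rates, dtype=float)
    if temps.shape != rates.shape:
        raise ValueError("temps_c and mean_rates must have the same length")
    ok = rates > 0
    if not ok.all():
        warnings.warn(
            f"dropping {np.sum(~ok)} non-positive mean rate(s); ln undefined",
            stacklevel=2,
        )
        temps, rates = temps[ok], rates[ok]
    n = temps.size
    if n < 3:
        raise ValueError(f"need >= 3 temperatures with positive mean rates, got {n}")
    x = boltzmann_x(temps, ref_c)
    res = stats.linregress(x, np.log(rates))
    tcrit = stats.t.ppf(0.975, n - 2)
    return ArrheniusFit(
        species=species,
        dataset=dataset,
        intercept=float(res.intercept),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        slope_ev=float(res.slope),
        slope_ci=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=int(n),
    )


def arrhenius_table(
    efficiencies: pd.DataFrame,
    rate_col: str = "mass_specific_rate_per_day",
    ref_c: float = T_REF_C,
) -> list[ArrheniusFit]:
    """Fit both datasets (size-matched; all data pooled) for every species.

    ``efficiencies`` is the per-replicate table produced by
    :mod:`thermoshred.shredding`; excluded replicates are ignored.
    """
    d = efficiencies
    if "excluded" in d.columns:
        d = d[~d["excluded"].astype(bool)]
    fits = []
    for species, sub in d.groupby("species", sort=False):
        for dataset, sel in (
            ("size-matched", sub[sub["size_class"] == "matched"]),
            ("all-data", sub),
        ):
            means = sel.groupby("temp_c")[rate_col].mean()
            fits.append(
                arrhenius_fit(
                    means.index.to_numpy(),
                    means.to_numpy(),
                    species=str(species),
                    dataset=dataset,
                    ref_c=ref_c,
                )
            )
    return fits


def fits_to_frame(fits: Iterable[ArrheniusFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "species": f.species,
                "dataset": f.dataset,
                "intercept": f.intercept,
                "intercept_ci_low": f.intercept_ci[0],
                "intercept_ci_high": f.intercept_ci[1],
                "activation_energy_ev": f.slope_ev,
                "slope_ci_low": f.slope_ci[0],
                "slope_ci_high": f.slope_ci[1],
                "r_squared": f.r_squared,
                "p_value": f.p_value,
                "n_points": f.n_points,
                "mte_band": mte_band_check(f),
            }
        )
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> list[ArrheniusFit]:
    return [
        ArrheniusFit(
            species=str(r["species"]),
            dataset=str(r["dataset"]),
            intercept=float(r["intercept"]),
            intercept_ci=(float(r["intercept_ci_low"]), float(r["intercept_ci_high"])),
            slope_ev=float(r["activation_energy_ev"]),
            slope_ci=(float(r["slope_ci_low"]), float(r["slope_ci_high"])),
            r_squared=float(r["r_squared"]),
            p_value=float(r["p_value"]),
            n_points=int(r["n_points"]),
        )
        for _, r in df.iterrows()
    ]


def mte_band_check(
    fit: ArrheniusFit, band: tuple[float, float] = MTE_BAND_EV
) -> str:
    """Classify an activation energy against the predicted 0.60-0.70 eV band.

    Returns ``"within"`` when the point estimate lies inside the band,
    ``"overlapping-CI"`` when only the 95% CI intersects it, and
    ``"outside"`` otherwise.
    """
    lo, hi = band
    if lo <= fit.slope_ev <= hi:
        return "within"
    ci_lo, ci_hi = fit.slope_ci
    if ci_lo <= hi and ci_hi >= lo:
        return "overlapping-CI"
    return "outside"


@dataclass
class AncovaResult:
    f_stat: float
    df: tuple[int, int]
    p: float
    compared_terms: str


def species_ancova(
    x: Sequence[float],
    ln_rates: Sequence[float],
    species_labels: Sequence[str],
    terms: str = "overall",
) -> AncovaResult:
    """Nested-model F test for a species effect on the Arrhenius relationship.

    The full model gives each species its own intercept and slope (4
    parameters for two species).  ``terms`` selects the reduced model:

    ``"overall"``
        intercept-only null; the F statistic is the overall regression F of
        the full species-by-temperature model, with numerator df 3 on a two
        species design (default);
    ``"species"``
        the common-line model (shared intercept and slope), isolating the
        species-linked terms with numerator df 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(ln_rates, dtype=float)
    labels = np.asarray(species_labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two species required, got {len(uniq)}")
    for sp in uniq:
        if np.sum(labels == sp) < 3:
            raise ValueError(f"species {sp!r} needs >= 3 points")
    ind = (labels == uniq[1]).astype(float)
    ones = np.ones_like(x)
    x_full = np.column_stack([ones, x, ind, ind * x])
    if terms == "overall":
        x_red = ones[:, None]
        desc = "species intercept + slope + common slope vs intercept-only"
    elif terms == "species":
        x_red = np.column_stack([ones, x])
        desc = "species-specific intercept and slope vs common line"
    else:
        raise ValueError(f"unknown terms mode {terms!r}")
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("singular design (no temperature variation within species?)")

    def _rss(design: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        return float(r @ r)

    rss_f = _rss(x_full)
    rss_r = _rss(x_red)
    dfn = x_full.shape[1] - x_red.shape[1]
    dfd = x.size - x_full.shape[1]
    if dfd < 1:
        raise ValueError("no residual degrees of freedom")
    f_stat = ((rss_r - rss_f) / dfn) / (rss_f / dfd)
    p = float(stats.f.sf(f_stat, dfn, dfd))
    return AncovaResult(f_stat=float(f_stat), df=(dfn, dfd), p=p, compared_terms=desc)
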