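"""Thermal-preferendum estimation and preference model comparison.

The "acute" method works in three steps: (1) the median recorded
temperature of each individual is its selected temperature (the median
avoids pseudoreplicating the 15 repeated observations); (2) the acute
preferendum of a species at an acclimation temperature is the mean of
those medians, with its standard error; (3) the final preferendum is the
temperature at which preference equals acclimation -- the intersection of
the fitted acute-preference line ``pref = a + b * T_acc`` with the 1:1
line, i.e. ``a / (1 - b)``.  A parametric bootstrap over the sampling
distribution of ``(a, b)`` supplies a confidence interval for this
nonlinear function of correlated estimates.

Control runs at uniform temperature are scored with a chi-squared test of
spatial uniformity over 10 cm track bins.  Candidate preference models
(species, acclimation, sex, and the species x acclimation interaction) are
fitted by least squares, ranked by small-sample AIC, and model-averaged
with Akaike weights over the set with delta AICc below a cutoff (default
4), using zero-substitution for terms a model omits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .records import ControlTrace, PositionTrace
from .specs import GradientSpec

__all__ = [
    "median_selected_temperature",
    "individual_medians",
    "AcutePreferendum",
    "acute_preferenda",
    "FinalPreferendum",
    "final_preferendum",
    "UniformityTest",
    "control_uniformity_test",
    "chi_squared_p",
    "aicc",
    "ModelComparisonTable",
    "akaike_weights_and_average",
    "fit_preference_models",
]


def median_selected_temperature(trace: PositionTrace) -> float:
    """Median of one individual's recorded temperatures.

    Even record counts give the mean of the two central values.
    """
    temps = trace.temperatures
    if temps.size == 0:
        raise ValueError(f"trace {trace.individual_id} has no records")
    return float(np.median(temps))


def individual_medians(traces: Iterable[PositionTrace]) -> pd.DataFrame:
    """One row per individual: id, species, sex, acclimation, median temp."""
    rows = [
        (
            tr.individual_id,
            tr.species,
            tr.sex,
            tr.acclimation_c,
            median_selected_temperature(tr),
        )
        for tr in traces
    ]
    return pd.DataFrame(
        rows, columns=["individual_id", "species", "sex", "acclimation_c", "median_c"]
    )


@dataclass
class AcutePreferendum:
    species: str
    acclimation_c: float
    mean_c: float
    se_c: float | None  # None (not zero) for singleton groups
    n: int


def acute_preferenda(medians: pd.DataFrame) -> list[AcutePreferendum]:
    """Group mean and SE of individual medians per species x acclimation."""
    out = []
    for (species, acc), grp in medians.groupby(["species", "acclimation_c"], sort=True):
        vals = grp["median_c"].to_numpy(dtype=float)
        n = vals.size
        if n == 0:
            raise ValueError(f"empty group {species} @ {acc} degC")
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else None
        out.append(
            AcutePreferendum(
                species=str(species),
                acclimation_c=float(acc),
                mean_c=float(vals.mean()),
                se_c=se,
                n=int(n),
            )
        )
    return out


@dataclass
class FinalPreferendum:
    species: str
    value_c: float
    intercept_c: float  # a of pref = a + b * T_acc
    slope: float  # b
    ci_c: tuple[float, float]


def final_preferendum(
    acutes: Sequence[AcutePreferendum],
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    slope_tol: float = 1e-6,
) -> FinalPreferendum:
    """Intersection of the acute-preference line with the 1:1 line.

    OLS of acute group means on acclimation temperature gives ``(a, b)``;
    the final preferendum is ``a / (1 - b)``.  The CI is a parametric
    bootstrap: draws from the bivariate normal sampling distribution of
    ``(a, b)``, mapped through the same ratio.  Requires at least three
    distinct acclimation temperatures (two for the line, one left over for
    an error estimate) and ``|1 - b|`` bounded away from zero.
    """
    species = {ac.species for ac in acutes}
    if len(species) != 1:
        raise ValueError(f"acutes must belong to one species, got {species}")
    t_acc = np.array([ac.acclimation_c for ac in acutes], dtype=float)
    y = np.array([ac.mean_c for ac in acutes], dtype=float)
    if np.unique(t_acc).size < 2:
        raise ValueError("need >= 2 distinct acclimation temperatures")
    design = np.column_stack([np.ones_like(t_acc), t_acc])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b = float(beta[0]), float(beta[1])
    if abs(1.0 - b) < slope_tol:
        raise ValueError(
            "acute preference line parallel to the 1:1 line; final preferendum diverges"
        )
    value = a / (1.0 - b)

    resid = y - design @ beta
    dof = t_acc.size - 2
    ci: tuple[float, float]
    if dof < 1:
        ci = (float("nan"), float("nan"))
    else:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(beta, cov, size=n_boot)
        denom = 1.0 - draws[:, 1]
        keep = np.abs(denom) > slope_tol
        vals = draws[keep, 0] / denom[keep]
        alpha = (1.0 - ci_level) / 2.0
        ci = (
            float(np.quantile(vals, alpha)),
            float(np.quantile(vals, 1.0 - alpha)),
        )
    return FinalPreferendum(
        species=species.pop(), value_c=float(value), intercept_c=a, slope=b, ci_c=ci
    )


def chi_squared_p(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-squared distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


@dataclass
class UniformityTest:
    species: str
    counts: np.ndarray
    chi2: float
    df: int
    p: float


def control_uniformity_test(
    traces: Sequence[ControlTrace],
    gradient: GradientSpec,
    species: str | None = None,
) -> UniformityTest:
    """Pearson chi-squared test of spatial uniformity over 10 cm track bins.

    Positions are binned half-open ``[lo, hi)`` (last bin closed) so every
    position maps to exactly one bin; the expected count is total / n_bins
    and df is n_bins - 1.  Warns when any expected count falls below 1.
    """
    positions = np.concatenate([np.asarray(tr.positions_cm, dtype=float) for tr in traces])
    if np.any(positions < 0) or np.any(positions > gradient.track_length_cm):
        raise ValueError("positions outside [0, track_length]")
    edges = np.arange(
        0.0, gradient.track_length_cm + gradient.bin_width_cm / 2, gradient.bin_width_cm
    )
    counts, _ = np.histogram(positions, bins=edges)
    n_bins = gradient.n_bins
    expected = positions.size / n_bins
    if expected < 1:
        warnings.warn(
            f"expected count per bin is {expected:.2f} < 1; chi-squared "
            "approximation unreliable",
            stacklevel=2,
        )
    if n_bins == 1:
        chi2, p = 0.0, 1.0
    else:
        chi2 = float(np.sum((counts - expected) ** 2) / expected)
        p = chi_squared_p(chi2, n_bins - 1)
    if species is None:
        species = traces[0].species if traces else ""
    return UniformityTest(
        species=species, counts=counts, chi2=chi2, df=n_bins - 1, p=p
    )


def aicc(neg2_loglik: float, k_params: int, n_obs: int) -> float:
    """Small-sample AIC: ``AIC + 2k(k+1)/(n-k-1)``."""
    if n_obs <= k_params + 1:
        raise ValueError(
            f"AICc undefined for n={n_obs} <= k+1={k_params + 1}"
        )
    aic = neg2_loglik + 2.0 * k_params
    return float(aic + 2.0 * k_params * (k_params + 1) / (n_obs - k_params - 1))


@dataclass
class ModelComparisonTable:
    """AICc ranking with Akaike weights and model-averaged coefficients.

    ``table`` has one row per candidate (sorted by AICc ascending) with
    columns model, k_params, aicc, delta_aicc, weight, retained; weights
    are normalised over the retained (delta < cutoff) set and NaN for the
    rest.  ``averaged_coefficients`` are zero-substitution weighted means.
    """

    table: pd.DataFrame
    averaged_coefficients: dict[str, float]
    delta_cutoff: float
    top_model: str = ""
    top_model_coefficients: pd.DataFrame | None = None


def akaike_weights_and_average(
    models: Sequence[tuple[str, int, float, Mapping[str, float]]],
    delta_cutoff: float = 4.0,
) -> ModelComparisonTable:
    """Rank (label, k, aicc, coefficients) tuples and model-average.

    Retains models with delta AICc below the cutoff (the best model is
    always retained), computes normalised Akaike weights
    ``exp(-delta/2) / sum``, and averages every coefficient across the
    retained set treating omitted terms as zero.
    """
    if not models:
        raise ValueError("at least one model required")
    labels = [m[0] for m in models]
    ks = np.array([m[1] for m in models], dtype=int)
    aiccs = np.array([m[2] for m in models], dtype=float)
    order = np.argsort(aiccs, kind="stable")
    delta = aiccs - aiccs.min()
    retained = delta < delta_cutoff
    rel = np.where(retained, np.exp(-delta / 2.0), 0.0)
    w = rel / rel.sum()
    weights = np.where(retained, w, np.nan)

    coef_names: list[str] = []
    for m in models:
        for name in m[3]:
            if name not in coef_names:
                coef_names.append(name)
    averaged = {
        name: float(
            sum(
                w[i] * float(models[i][3].get(name, 0.0))
                for i in range(len(models))
                if retained[i]
            )
        )
        for name in coef_names
    }
    table = pd.DataFrame(
        {
            "model": [labels[i] for i in order],
            "k_params": ks[order],
            "aicc": aiccs[order],
            "delta_aicc": delta[order],
            "weight": weights[order],
            "retained": retained[order],
        }
    )
    return ModelComparisonTable(
        table=table.reset_index(drop=True),
        averaged_coefficients=averaged,
        delta_cutoff=delta_cutoff,
        top_model=labels[order[0]],
    )


_TERM_LABELS = {
    "species": "Species",
    "acclimation_c": "Acc.Temp",
    "sex": "Sex",
    "body_size": "Body size",
    "species:acclimation_c": "Species x Acc.Temp",
}


def fit_preference_models(
    data: pd.DataFrame,
    transform=None,
    delta_cutoff: float = 4.0,
    include_size: bool | None = None,
) -> ModelComparisonTable:
    """Fit the candidate preference-model set and rank it by AICc.

    ``data`` holds one row per individual with columns ``median_c``,
    ``species``, ``acclimation_c``, ``sex`` and optionally ``body_size``.
    The candidate set is every additive subset of the available factors
    plus, whenever both species and acclimation are present, the model with
    their interaction.  Models are fitted by ordinary least squares with a
    Gaussian likelihood (k counts the residual variance); the top model's
    coefficient table (estimate, SE, t, p) is attached.  ``transform`` is
    an optional monotone transform applied to the medians before fitting
    (hook for heavy-tailed residuals); default is none.
    """
    df = data.copy()
    df["_y"] = transform(df["median_c"]) if transform is not None else df["median_c"]
    n = len(df)

    pool: list[str] = []
    if df["species"].nunique() >= 2:
        pool.append("species")
    else:
        warnings.warn("single species: species terms dropped from candidate set",
                      stacklevel=2)
    if df["acclimation_c"].nunique() >= 2:
        pool.append("acclimation_c")
    if "sex" in df.columns and df["sex"].nunique() >= 2:
        pool.append("sex")
    if include_size is None:
        include_size = "body_size" in df.columns
    if include_size and "body_size" in df.columns:
        pool.append("body_size")

    term_sets: list[tuple[str, ...]] = [()]
    for r in range(1, len(pool) + 1):
        for combo in combinations(pool, r):
            term_sets.append(combo)
            if "species" in combo and "acclimation_c" in combo:
                term_sets.append(combo + ("species:acclimation_c",))

    fitted = []
    results = {}
    for terms in term_sets:
        rhs = " + ".join(terms) if terms else "1"
        res = smf.ols(f"_y ~ {rhs}", data=df).fit()
        k = int(res.df_model) + 2  # coefficients incl. intercept, plus sigma
        label = (
            " + ".join(_TERM_LABELS.get(t, t) for t in terms) if terms else "Intercept only"
        )
        fitted.append((label, k, aicc(-2.0 * res.llf, k, n), dict(res.params)))
        results[label] = res
    out = akaike_weights_and_average(fitted, delta_cutoff=delta_cutoff)
    top = results[out.top_model]
    out.top_model_coefficients = pd.DataFrame(
        {
            "estimate": top.params,
            "se": top.bse,
            "t": top.tvalues,
            "p": top.pvalues,
        }
    )
    return out
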