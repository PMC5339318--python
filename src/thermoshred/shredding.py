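"""Shredding efficiencies, the PCA body-size index, and factorial ANOVA.

Leaf shredding efficiency is the dry leaf mass consumed per amphipod-day,
where an amphipod-day is one animal alive for one (24 h) day of the 72 h
trial.  The default convention counts the day on which an animal was found
dead as a day it fed ("partial" -- a death at the first check contributes
one amphipod-day); the alternative "none" counts only fully survived days.
Replicates containing a moulted animal are excluded (moulting suppresses
feeding), as are replicates with zero amphipod-days.

Wet mass and body length are collapsed to a single body-size index by PCA
on the standardised 2 x 2 correlation matrix; PC1 explains ``(1 + r) / 2``
of the variance.  Size matching between species is verified with a one-way
ANOVA on PC1 scores, and efficiency is analysed with a species x
temperature two-way ANOVA (temperature categorical, Type-I sums of squares
on the balanced design, non-significant interaction removed by stepwise
deletion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .records import ShreddingTrial

__all__ = [
    "amphipod_days",
    "EfficiencyRecord",
    "shredding_efficiency",
    "control_loss_fraction",
    "efficiency_table",
    "BodySizeIndex",
    "body_size_index",
    "AnovaTable",
    "size_match_test",
    "two_way_anova",
    "SurvivalEstimate",
    "survival_rate",
    "survival_table",
]


def amphipod_days(
    trial: ShreddingTrial,
    trial_days: int = 3,
    convention: str = "partial",
) -> int:
    """Number of surviving amphipods per day, summed over the trial.

    ``convention="partial"`` (default): an animal found dead at the day-d
    check fed for part of day d and contributes d days.  ``"none"``: it
    contributes d - 1 fully survived days.
    """
    if trial.is_control:
        raise ValueError(f"{trial.replicate_id}: control pots have no amphipod-days")
    if convention not in ("partial", "none"):
        raise ValueError(f"unknown death-day convention {convention!r}")
    total = 0
    for an in trial.animals:
        if an.death_day is None:
            total += trial_days
        elif convention == "partial":
            total += an.death_day
        else:
            total += an.death_day - 1
    return total


@dataclass
class EfficiencyRecord:
    replicate_id: str
    species: str
    temp_c: float
    size_class: str
    amphipod_days: int
    consumed_mg: float
    efficiency_mg_per_ad: float | None  # mg dry leaf per amphipod-day
    mass_specific_rate_per_day: float | None  # g leaf / g body / day
    mean_mass_g: float | None
    excluded: bool
    reason: str = ""


def shredding_efficiency(
    trial: ShreddingTrial,
    control_loss: float = 0.0,
    trial_days: int = 3,
    convention: str = "partial",
) -> EfficiencyRecord:
    """Per-replicate shredding efficiency, standardised by amphipod-days.

    ``efficiency = max(0, (initial - final) - control_loss * initial) / amphipod_days``.
    Replicates with a moulted animal or zero amphipod-days are returned as
    excluded records (never an infinite efficiency).  The mass-specific
    rate divides by the pot's mean wet body mass, giving g leaf per g body
    per day -- the unit the Arrhenius fits run on.
    """
    if trial.is_control:
        raise ValueError(f"{trial.replicate_id}: controls carry no efficiency")
    mean_mass = (
        float(np.mean([an.wet_mass_g for an in trial.animals]))
        if trial.animals
        else None
    )
    base = dict(
        replicate_id=trial.replicate_id,
        species=trial.species,
        temp_c=trial.temp_c,
        size_class=trial.size_class,
        mean_mass_g=mean_mass,
    )
    if any(an.moulted for an in trial.animals):
        return EfficiencyRecord(
            **base,
            amphipod_days=amphipod_days(trial, trial_days, convention),
            consumed_mg=np.nan,
            efficiency_mg_per_ad=None,
            mass_specific_rate_per_day=None,
            excluded=True,
            reason="moult",
        )
    ad = amphipod_days(trial, trial_days, convention)
    if ad == 0:
        return EfficiencyRecord(
            **base,
            amphipod_days=0,
            consumed_mg=np.nan,
            efficiency_mg_per_ad=None,
            mass_specific_rate_per_day=None,
            excluded=True,
            reason="zero amphipod-days",
        )
    consumed = max(
        0.0,
        (trial.leaf_mass_initial_mg - trial.leaf_mass_final_mg)
        - control_loss * trial.leaf_mass_initial_mg,
    )
    eff = consumed / ad
    msr = (consumed / 1000.0) / mean_mass / ad if mean_mass else None
    return EfficiencyRecord(
        **base,
        amphipod_days=ad,
        consumed_mg=consumed,
        efficiency_mg_per_ad=eff,
        mass_specific_rate_per_day=msr,
        excluded=False,
    )


def control_loss_fraction(trials: Iterable[ShreddingTrial]) -> float:
    """Mean fractional leaf-mass loss across control (animal-free) pots."""
    losses = [
        (t.leaf_mass_initial_mg - t.leaf_mass_final_mg) / t.leaf_mass_initial_mg
        for t in trials
        if t.is_control and t.leaf_mass_initial_mg > 0
    ]
    return float(np.mean(losses)) if losses else 0.0


def efficiency_table(
    trials: Sequence[ShreddingTrial],
    control_loss: float | None = None,
    trial_days: int = 3,
    convention: str = "partial",
    loss_threshold: float = 0.02,
) -> pd.DataFrame:
    """Efficiency records for every non-control pot, as a DataFrame.

    When ``control_loss`` is None the mean control-pot loss is computed
    and, following the discount rule, applied as zero when it is below the
    2% threshold (microbial breakdown and leaching negligible).
    """
    if control_loss is None:
        observed = control_loss_fraction(trials)
        control_loss = 0.0 if observed < loss_threshold else observed
    recs = [
        shredding_efficiency(t, control_loss, trial_days, convention)
        for t in trials
        if not t.is_control
    ]
    return pd.DataFrame(
        [
            {
                "replicate_id": r.replicate_id,
                "species": r.species,
                "temp_c": r.temp_c,
                "size_class": r.size_class,
                "amphipod_days": r.amphipod_days,
                "consumed_mg": r.consumed_mg,
                "efficiency_mg_per_ad": r.efficiency_mg_per_ad,
                "mass_specific_rate_per_day": r.mass_specific_rate_per_day,
                "mean_mass_g": r.mean_mass_g,
                "excluded": r.excluded,
                "reason": r.reason,
            }
            for r in recs
        ]
    )


@dataclass
class BodySizeIndex:
    scores: np.ndarray  # PC1 score per animal, zero mean
    variance_explained: float
    loadings: tuple[float, float]  # (length, mass), both positive


def body_size_index(lengths: Sequence[float], masses: Sequence[float]) -> BodySizeIndex:
    """PC1 of standardised (length, mass): a single index of body size.

    With two standardised variables the leading eigenvalue of the
    correlation matrix is ``1 + r``, so PC1 explains ``(1 + r) / 2`` of the
    variance.  Loading signs are fixed so both variables load positively
    (bigger animal = larger score).
    """
    length = np.asarray(lengths, dtype=float)
    mass = np.asarray(masses, dtype=float)
    if length.size != mass.size:
        raise ValueError("lengths and masses must have the same size")
    if length.size < 3:
        raise ValueError("need at least 3 animals for a PCA index")
    if np.std(length) == 0 or np.std(mass) == 0:
        raise ValueError("zero variance in length or mass")
    zl = (length - length.mean()) / length.std(ddof=1)
    zm = (mass - mass.mean()) / mass.std(ddof=1)
    r = float(np.corrcoef(zl, zm)[0, 1])
    corr = np.array([[1.0, r], [r, 1.0]])
    eigvals, eigvecs = np.linalg.eigh(corr)
    vec = eigvecs[:, -1]
    if vec.sum() < 0:
        vec = -vec
    scores = zl * vec[0] + zm * vec[1]
    return BodySizeIndex(
        scores=scores - scores.mean(),
        variance_explained=float(eigvals[-1] / 2.0),
        loadings=(float(vec[0]), float(vec[1])),
    )


@dataclass
class AnovaTable:
    rows: pd.DataFrame  # source, df, sum_sq, F, p
    design: dict


def size_match_test(scores: Sequence[float], species: Sequence[str]) -> AnovaTable:
    """One-way ANOVA of PC1 scores by species; p > 0.05 = matching succeeded."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(species)
    groups = [scores[labels == sp] for sp in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two species groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    f_stat, p = stats.f_oneway(*groups)
    k, n = len(groups), scores.size
    rows = pd.DataFrame(
        [
            {"source": "species", "df": k - 1, "F": float(f_stat), "p": float(p)},
            {"source": "residual", "df": n - k, "F": np.nan, "p": np.nan},
        ]
    )
    return AnovaTable(
        rows=rows,
        design={"factors": {"species": list(pd.unique(labels))},
                "matched": bool(p > 0.05)},
    )


def two_way_anova(
    records: pd.DataFrame,
    response: str = "efficiency_mg_per_ad",
    alpha: float = 0.05,
    stepwise: bool = True,
) -> AnovaTable:
    """Species x temperature ANOVA on efficiency records.

    Temperature enters as a categorical factor.  Balanced designs use
    Type-I sums of squares; empty or uneven cells trigger a warning and a
    Type-II fallback.  With ``stepwise`` (default) a non-significant
    interaction (p > alpha) is removed and the main effects re-tested; the
    dropped interaction row is kept in the table, flagged in ``design``.
    """
    d = records
    if "excluded" in d.columns:
        d = d[~d["excluded"].astype(bool)]
    d = d.dropna(subset=[response]).copy()
    cells = d.groupby(["species", "temp_c"], observed=True).size()
    if cells.empty or (cells < 2).any():
        raise ValueError("need >= 2 usable replicates per species x temperature cell")
    balanced = cells.nunique() == 1
    typ = 1 if balanced else 2
    if not balanced:
        warnings.warn(
            "unbalanced species x temperature design; using Type-II sums of squares",
            stacklevel=2,
        )
    full = smf.ols(f"{response} ~ species * C(temp_c)", data=d).fit()
    if full.df_resid < 1 or full.mse_resid < 1e-12:
        raise ValueError("residual variation is (numerically) zero; F undefined")
    tab_full = sm.stats.anova_lm(full, typ=typ)
    inter_label = "species:C(temp_c)"
    p_inter = float(tab_full.loc[inter_label, "PR(>F)"])
    interaction_dropped = False
    if stepwise and p_inter > alpha:
        interaction_dropped = True
        reduced = smf.ols(f"{response} ~ species + C(temp_c)", data=d).fit()
        tab = sm.stats.anova_lm(reduced, typ=typ)
    else:
        tab = tab_full

    def _row(name: str, label: str, table: pd.DataFrame) -> dict:
        return {
            "source": label,
            "df": int(table.loc[name, "df"]),
            "sum_sq": float(table.loc[name, "sum_sq"]),
            "F": float(table.loc[name, "F"]) if not np.isnan(table.loc[name, "F"]) else np.nan,
            "p": float(table.loc[name, "PR(>F)"])
            if not np.isnan(table.loc[name, "PR(>F)"])
            else np.nan,
        }

    rows = [
        _row("species", "species", tab),
        _row("C(temp_c)", "temperature", tab),
        _row(inter_label, "species:temperature", tab_full),
        _row("Residual", "residual", tab),
    ]
    return AnovaTable(
        rows=pd.DataFrame(rows),
        design={
            "factors": {
                "species": sorted(d["species"].unique().tolist()),
                "temp_c": sorted(d["temp_c"].unique().tolist()),
            },
            "balanced": bool(balanced),
            "ss_type": typ,
            "interaction_dropped": interaction_dropped,
        },
    )


@dataclass
class SurvivalEstimate:
    species: str
    temp_c: float
    n_animals: int
    n_survived: int
    survival: float
    ci: tuple[float, float]  # Wilson score 95% CI


def survival_rate(
    trials: Iterable[ShreddingTrial], species: str, temp_c: float
) -> SurvivalEstimate:
    """Fraction of animals alive at 72 h in one species x temperature cell."""
    animals = [
        an
        for t in trials
        if not t.is_control and t.species == species and t.temp_c == temp_c
        for an in t.animals
    ]
    if not animals:
        raise ValueError(f"no animals for {species} at {temp_c} degC")
    n = len(animals)
    alive = sum(an.survived for an in animals)
    lo, hi = proportion_confint(alive, n, alpha=0.05, method="wilson")
    return SurvivalEstimate(
        species=species,
        temp_c=temp_c,
        n_animals=n,
        n_survived=alive,
        survival=alive / n,
        ci=(float(lo), float(hi)),
    )


def survival_table(trials: Sequence[ShreddingTrial]) -> pd.DataFrame:
    """Survival estimates for every species x temperature cell."""
    cells = sorted(
        {(t.species, t.temp_c) for t in trials if not t.is_control and t.animals}
    )
    rows = []
    for species, temp in cells:
        est = survival_rate(trials, species, temp)
        rows.append(
            {
                "species": est.species,
                "temp_c": est.temp_c,
                "n_animals": est.n_animals,
                "n_survived": est.n_survived,
                "survival": est.survival,
                "ci_low": est.ci[0],
                "ci_high": est.ci[1],
            }
        )
    return pd.DataFrame(rows)
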