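"""Seeded generators for gradient traces, body sizes, and shredding trials.

Every generator takes an integer seed (or a ``numpy.random.Generator``) and
is byte-reproducible: the same seed and configuration give identical
outputs.  The generators emulate the two experimental designs with known
ground truth so that every downstream estimator can be tested by parameter
recovery:

* position traces are i.i.d. draws from a normal centred on the species'
  acute preference line ``a + b * T_acc``, truncated to the gradient range
  (downstream analyses use only the marginal distribution of recorded
  temperatures, so no locomotion model is needed);
* control traces are uniform positions along the track;
* body sizes are bivariate lognormal (length, wet mass) with a target
  correlation on the log scale;
* shredding trials draw leaf batches, temperature-dependent daily deaths
  (logistic link), moult flags, and mass-specific daily consumption
  ``m * exp(ln_rate_intercept + E_a * x(T) + noise)``.

An animal found dead at the day-``d`` check is treated as having fed
through day ``d`` (the "partial day counts" convention, mirrored by the
default amphipod-day accounting in :mod:`thermoshred.shredding`).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import truncnorm

from .mte_arrhenius import boltzmann_x
from .records import (
    Animal,
    ControlTrace,
    PositionTrace,
    ShreddingTrial,
    traces_to_frame,
    trials_to_frame,
)
from .specs import DesignSpec, GradientSpec, SpeciesParams

__all__ = [
    "generate_position_traces",
    "generate_control_traces",
    "generate_body_sizes",
    "generate_shredding_trials",
    "write_tables",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _slug(name: str) -> str:
    return name.replace(". ", "").replace(" ", "-").lower()


def generate_position_traces(
    params: SpeciesParams,
    design: DesignSpec,
    gradient: GradientSpec,
    seed,
) -> list[PositionTrace]:
    """One trace per individual: ``n_obs`` records on the 3-minute schedule.

    Recorded temperatures are drawn from a normal with mean
    ``a + b * T_acc`` (plus any female offset) and sd ``pref_sd_c``,
    truncated to the gradient range.  Raises if an acclimation temperature
    falls outside the gradient.
    """
    for t_acc in design.acclimation_temps:
        if not gradient.contains(t_acc):
            raise ValueError(
                f"acclimation temperature {t_acc} degC outside gradient range "
                f"[{gradient.temp_cold_c}, {gradient.temp_hot_c}]"
            )
    rng = _as_rng(seed)
    minutes = design.obs_interval_min * np.arange(1, design.n_obs + 1)
    lo, hi = gradient.temp_cold_c, gradient.temp_hot_c
    traces: list[PositionTrace] = []
    counter = 0
    slug = _slug(params.name)
    for t_acc in design.acclimation_temps:
        base = params.acute_preferendum(t_acc)
        for i in range(design.n_per_acclimation):
            sex = "M" if i % 2 == 0 else "F"
            mu = base + (params.sex_effect_c if sex == "F" else 0.0)
            if params.pref_sd_c < 1e-12:
                temps = np.full(design.n_obs, np.clip(mu, lo, hi))
            else:
                a = (lo - mu) / params.pref_sd_c
                b = (hi - mu) / params.pref_sd_c
                temps = truncnorm.rvs(
                    a, b, loc=mu, scale=params.pref_sd_c,
                    size=design.n_obs, random_state=rng,
                )
            traces.append(
                PositionTrace(
                    individual_id=f"{slug}-acc{t_acc:g}-{i + 1:02d}",
                    species=params.name,
                    sex=sex,
                    acclimation_c=float(t_acc),
                    track_id=f"track{counter % 4 + 1}",
                    run_time=f"run{counter // 2 + 1:03d}",
                    records=list(zip(minutes, temps)),
                )
            )
            counter += 1
    return traces


def generate_control_traces(
    n_animals: int,
    n_records: int,
    gradient: GradientSpec,
    seed,
    species: str = "control",
) -> list[ControlTrace]:
    """Uniform positions along the track: the no-preference null.

    Defaults in the pipeline are 6 animals x 30 records = 180 records per
    species, matching the control design.
    """
    if n_animals < 1 or n_records < 1:
        raise ValueError("n_animals and n_records must be >= 1")
    rng = _as_rng(seed)
    positions = rng.uniform(0.0, gradient.track_length_cm, size=(n_animals, n_records))
    return [
        ControlTrace(
            individual_id=f"{_slug(species)}-ctrl-{i + 1:02d}",
            species=species,
            positions_cm=list(positions[i]),
        )
        for i in range(n_animals)
    ]


def generate_body_sizes(
    params: SpeciesParams,
    n: int,
    seed,
    size_class: str = "full",
) -> np.ndarray:
    """``(n, 2)`` array of (length mm, wet mass g), bivariate lognormal.

    The coefficient of variation ``size_cv`` applies to both variables and
    ``length_mass_corr`` is the correlation on the standardised log scale.
    Size-matched draws use the common matched means instead of the species'
    own means.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if size_class == "matched":
        means = (params.matched_mean_length_mm, params.matched_mean_mass_g)
    else:
        means = (params.mean_length_mm, params.mean_mass_g)
    sigma = np.sqrt(np.log1p(params.size_cv**2))
    r = params.length_mass_corr
    cov = sigma**2 * np.array([[1.0, r], [r, 1.0]])
    mu = np.log(means) - sigma**2 / 2.0
    z = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    return np.exp(z)


def generate_shredding_trials(
    params_by_species: Mapping[str, SpeciesParams],
    design: DesignSpec,
    seed,
    ref_c: float = 15.0,
) -> list[ShreddingTrial]:
    """Full factorial of species x temperature x size class x replicate pots.

    Per pot: a leaf batch ``N(leaf_mass_mean, leaf_mass_sd^2)`` truncated
    positive; per animal a logistic daily death draw, a moult flag, and
    mass-specific lognormal consumption on every day it is (partly) alive.
    Control pots (``n_control_per_temp`` per temperature) contain no animals
    and lose a uniform 0-2% of the initial leaf mass.  Pots whose leaf discs
    are exhausted are floored at zero final mass and flagged ``depleted``.
    """
    rng = _as_rng(seed)
    trials: list[ShreddingTrial] = []
    mean_mg, sd_mg = design.leaf_mass_mean_mg, design.leaf_mass_sd_mg

    def _leaf_batch() -> float:
        if sd_mg < 1e-12:
            return mean_mg
        a = (0.0 - mean_mg) / sd_mg
        return float(
            truncnorm.rvs(a, np.inf, loc=mean_mg, scale=sd_mg, random_state=rng)
        )

    for species, params in params_by_species.items():
        slug = _slug(species)
        for temp in design.experimental_temps:
            p_death = params.daily_death_prob(temp)
            if not 0.0 <= p_death <= 1.0:
                raise ValueError(
                    f"mortality parameters give daily death probability "
                    f"{p_death} at {temp} degC"
                )
            x = boltzmann_x(temp, ref_c)
            for size_class in ("matched", "full"):
                for rep in range(design.n_replicates):
                    sizes = generate_body_sizes(
                        params, design.animals_per_pot, rng, size_class=size_class
                    )
                    initial = _leaf_batch()
                    animals: list[Animal] = []
                    consumed = 0.0
                    for length_mm, mass_g in sizes:
                        death_day: int | None = None
                        for day in range(1, design.trial_days + 1):
                            if rng.random() < p_death:
                                death_day = day
                                break
                        days_fed = design.trial_days if death_day is None else death_day
                        for _ in range(days_fed):
                            noise = (
                                rng.normal(0.0, params.rate_noise_sd)
                                if params.rate_noise_sd > 0
                                else 0.0
                            )
                            rate = np.exp(
                                params.ln_rate_intercept
                                + params.activation_energy_ev * x
                                + noise
                            )
                            consumed += mass_g * rate * 1000.0  # g -> mg dry leaf
                        animals.append(
                            Animal(
                                length_mm=float(length_mm),
                                wet_mass_g=float(mass_g),
                                death_day=death_day,
                                moulted=bool(rng.random() < params.moult_prob),
                            )
                        )
                    final = initial - consumed
                    depleted = final < 0.0
                    trials.append(
                        ShreddingTrial(
                            replicate_id=f"{slug}-t{temp:g}-{size_class}-r{rep + 1:02d}",
                            species=species,
                            temp_c=float(temp),
                            size_class=size_class,
                            animals=animals,
                            leaf_mass_initial_mg=initial,
                            leaf_mass_final_mg=max(0.0, final),
                            depleted=bool(depleted),
                        )
                    )
    for temp in design.experimental_temps:
        for j in range(design.n_control_per_temp):
            initial = _leaf_batch()
            loss = rng.uniform(0.0, 0.02)
            trials.append(
                ShreddingTrial(
                    replicate_id=f"control-t{temp:g}-r{j + 1:02d}",
                    species="control",
                    temp_c=float(temp),
                    size_class="control",
                    animals=[],
                    leaf_mass_initial_mg=initial,
                    leaf_mass_final_mg=initial * (1.0 - loss),
                    is_control=True,
                )
            )
    return trials


def write_tables(
    traces: Sequence[PositionTrace],
    trials: Sequence[ShreddingTrial],
    outdir,
    ground_truth: dict | None = None,
) -> None:
    """Write the two canonical CSVs plus a ground-truth parameter sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    traces_to_frame(traces).to_csv(out / "position_traces.csv", index=False)
    trials_to_frame(trials).to_csv(out / "shredding_trials.csv", index=False)
    if ground_truth is not None:
        with open(out / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(ground_truth, fh, sort_keys=True)
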