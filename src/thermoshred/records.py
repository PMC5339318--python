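"""Record containers and their CSV (DataFrame) representations.

Two canonical tables travel through the pipeline:

``position_traces.csv``
    one row per observation of an animal on the gradient track
    (individual_id, species, sex, acclimation_c, track_id, run_time,
    obs_minute, recorded_temp_c);
``shredding_trials.csv``
    one row per animal per pot, with the pot-level leaf masses repeated
    (replicate_id, species, temp_c, size_class, animal_index, length_mm,
    wet_mass_g, death_day, moulted, is_control, leaf_mass_initial_mg,
    leaf_mass_final_mg).  Control pots contain no animals and carry a single
    row with empty animal fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionTrace",
    "ControlTrace",
    "Animal",
    "ShreddingTrial",
    "traces_to_frame",
    "frame_to_traces",
    "trials_to_frame",
    "frame_to_trials",
    "TRACE_COLUMNS",
    "TRIAL_COLUMNS",
]

TRACE_COLUMNS = [
    "individual_id",
    "species",
    "sex",
    "acclimation_c",
    "track_id",
    "run_time",
    "obs_minute",
    "recorded_temp_c",
]

TRIAL_COLUMNS = [
    "replicate_id",
    "species",
    "temp_c",
    "size_class",
    "animal_index",
    "length_mm",
    "wet_mass_g",
    "death_day",
    "moulted",
    "is_control",
    "leaf_mass_initial_mg",
    "leaf_mass_final_mg",
]


@dataclass
class PositionTrace:
    """One individual's timed sequence of recorded water temperatures."""

    individual_id: str
    species: str
    sex: str
    acclimation_c: float
    track_id: str
    run_time: str
    records: list[tuple[float, float]]  # (obs_minute, recorded_temp_c)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(
                f"trace {self.individual_id}: needs >= 2 records, "
                f"got {len(self.records)}"
            )
        minutes = [m for m, _ in self.records]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise ValueError(
                f"trace {self.individual_id}: obs_minute must be strictly increasing"
            )

    @property
    def temperatures(self) -> np.ndarray:
        return np.asarray([t for _, t in self.records], dtype=float)

    @property
    def minutes(self) -> np.ndarray:
        return np.asarray([m for m, _ in self.records], dtype=float)


@dataclass
class ControlTrace:
    """Positions (cm along the track) of one animal under uniform temperature."""

    individual_id: str
    species: str
    positions_cm: list[float]

    def __post_init__(self) -> None:
        if len(self.positions_cm) < 1:
            raise ValueError("control trace needs at least one position")


@dataclass
class Animal:
    """One amphipod in a shredding pot."""

    length_mm: float
    wet_mass_g: float
    death_day: int | None = None  # 1-based day of the check at which found dead
    moulted: bool = False

    @property
    def survived(self) -> bool:
        return self.death_day is None


@dataclass
class ShreddingTrial:
    """One replicate pot of the 72 h shredding experiment."""

    replicate_id: str
    species: str
    temp_c: float
    size_class: str  # "matched" | "full" | "control"
    animals: list[Animal]
    leaf_mass_initial_mg: float
    leaf_mass_final_mg: float
    is_control: bool = False
    depleted: bool = False  # leaf discs fully consumed (final mass floored at 0)

    def __post_init__(self) -> None:
        if self.leaf_mass_initial_mg < 0 or self.leaf_mass_final_mg < 0:
            raise ValueError(f"{self.replicate_id}: leaf masses must be >= 0")
        if self.is_control and self.animals:
            raise ValueError(f"{self.replicate_id}: control pots have zero animals")


def traces_to_frame(traces: Iterable[PositionTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for minute, temp in tr.records:
            rows.append(
                (
                    tr.individual_id,
                    tr.species,
                    tr.sex,
                    tr.acclimation_c,
                    tr.track_id,
                    tr.run_time,
                    minute,
                    temp,
                )
            )
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def frame_to_traces(df: pd.DataFrame) -> list[PositionTrace]:
    traces = []
    for ind, grp in df.groupby("individual_id", sort=False):
        grp = grp.sort_values("obs_minute")
        first = grp.iloc[0]
        traces.append(
            PositionTrace(
                individual_id=str(ind),
                species=str(first["species"]),
                sex=str(first["sex"]),
                acclimation_c=float(first["acclimation_c"]),
                track_id=str(first["track_id"]),
                run_time=str(first["run_time"]),
                records=list(
                    zip(grp["obs_minute"].astype(float), grp["recorded_temp_c"].astype(float))
                ),
            )
        )
    return traces


def trials_to_frame(trials: Iterable[ShreddingTrial]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        if tr.is_control or not tr.animals:
            rows.append(
                (
                    tr.replicate_id,
                    tr.species,
                    tr.temp_c,
                    tr.size_class,
                    np.nan,
                    np.nan,
                    np.nan,
                    np.nan,
                    False,
                    tr.is_control,
                    tr.leaf_mass_initial_mg,
                    tr.leaf_mass_final_mg,
                )
            )
            continue
        for idx, an in enumerate(tr.animals, start=1):
            rows.append(
                (
                    tr.replicate_id,
                    tr.species,
                    tr.temp_c,
                    tr.size_class,
                    idx,
                    an.length_mm,
                    an.wet_mass_g,
                    np.nan if an.death_day is None else an.death_day,
                    an.moulted,
                    tr.is_control,
                    tr.leaf_mass_initial_mg,
                    tr.leaf_mass_final_mg,
                )
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[ShreddingTrial]:
    trials = []
    for rep, grp in df.groupby("replicate_id", sort=False):
        first = grp.iloc[0]
        is_control = bool(first["is_control"])
        animals: list[Animal] = []
        if not is_control:
            for _, row in grp.sort_values("animal_index").iterrows():
                if pd.isna(row["animal_index"]):
                    continue
                dd = row["death_day"]
                animals.append(
                    Animal(
                        length_mm=float(row["length_mm"]),
                        wet_mass_g=float(row["wet_mass_g"]),
                        death_day=None if pd.isna(dd) else int(dd),
                        moulted=bool(row["moulted"]),
                    )
                )
        trials.append(
            ShreddingTrial(
                replicate_id=str(rep),
                species=str(first["species"]),
                temp_c=float(first["temp_c"]),
                size_class=str(first["size_class"]),
                animals=animals,
                leaf_mass_initial_mg=float(first["leaf_mass_initial_mg"]),
                leaf_mass_final_mg=float(first["leaf_mass_final_mg"]),
                is_control=is_control,
            )
        )
    return trials
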