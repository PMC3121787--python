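"""Synthetic diet-switch experiments.

Emulates a captive feeding experiment on 40 farmed arctic foxes with a
balanced 2x2 population structure (20/20 females/males, 20/20
adults/yearlings): animals equilibrated on one diet are shifted to a
marine diet at day 0 and blood is sampled on days
0, 4, 7, 11, 15, 19, 23, 28, 35, 55 and 70, while a control arm stays
on the terrestrial diet.  Trajectories follow the one-compartment
incorporation model with an individual Gaussian random effect on the
log-rate, optional sex/age shifts of the log-rate, and i.i.d. Gaussian
measurement error (default 0.2 permil, typical bulk-isotope analytical
precision).

A companion generator produces diet-tissue discrimination records
(tissue x diet x sex x age cells with a shared individual intercept),
so the discrimination analyses can be exercised without any real data.
All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import (OneCompartmentParams, RandomEffectsSpec,
                       phi3_for_half_life, predict_one_compartment)

__all__ = [
    "FULL_SCHEDULE",
    "PopulationSpec",
    "TrajectoryTruth",
    "DiscriminationTruth",
    "DEFAULT_DIET_SIGNATURES",
    "default_trajectory_truth",
    "default_discrimination_truth",
    "simulate_trajectories",
    "simulate_control_group",
    "simulate_discrimination_dataset",
]

#: Blood sampling days after the diet shift.
FULL_SCHEDULE: tuple[float, ...] = (0, 4, 7, 11, 15, 19, 23, 28, 35, 55, 70)

SEXES = ("F", "M")
AGES = ("adult", "yearling")
DIETS = ("mix", "terrestrial", "marine")
TISSUES = ("blood_cells", "plasma", "liver", "muscle", "fur", "nail")
ISOTOPES = ("d13C", "d15N")

#: Plausible bulk diet signatures (permil) for the three experimental
#: diets; configuration defaults only, replaceable via the config file.
DEFAULT_DIET_SIGNATURES = pd.DataFrame([
    {"diet": "mix", "isotope": "d13C", "delta_permil": -22.5, "c_n_ratio": 4.2},
    {"diet": "mix", "isotope": "d15N", "delta_permil": 8.5, "c_n_ratio": 4.2},
    {"diet": "terrestrial", "isotope": "d13C", "delta_permil": -26.0, "c_n_ratio": 4.5},
    {"diet": "terrestrial", "isotope": "d15N", "delta_permil": 5.0, "c_n_ratio": 4.5},
    {"diet": "marine", "isotope": "d13C", "delta_permil": -19.0, "c_n_ratio": 3.8},
    {"diet": "marine", "isotope": "d15N", "delta_permil": 12.5, "c_n_ratio": 3.8},
])


@dataclass(frozen=True)
class PopulationSpec:
    """Experimental population layout.

    Defaults mirror the study design: 40 animals, balanced sexes and
    ages, 20 shifted to the marine diet and the remainder kept on the
    terrestrial diet as controls.
    """

    n_individuals: int = 40
    n_shifted: int = 20
    sex_ratio: float = 0.5
    age_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.n_individuals < 0 or self.n_shifted < 0:
            raise ValueError("counts must be non-negative")
        if self.n_shifted > self.n_individuals:
            raise ValueError("n_shifted cannot exceed n_individuals")
        if not (0.0 <= self.sex_ratio <= 1.0 and 0.0 <= self.age_ratio <= 1.0):
            raise ValueError("ratios must lie in [0, 1]")

    @property
    def n_control(self) -> int:
        return self.n_individuals - self.n_shifted


def _assign_labels(n: int, spec: PopulationSpec, prefix: str) -> pd.DataFrame:
    """Deterministic balanced assignment of ids, sex and age."""
    n_f = round(n * spec.sex_ratio)
    sexes = ["F"] * n_f + ["M"] * (n - n_f)
    n_a = round(n * spec.age_ratio)
    # Interleave ages within each sex so 2x2 cells stay balanced.
    ages = []
    count_a = 0
    for i in range(n):
        if count_a < n_a and (i % 2 == 0 or n - i <= n_a - count_a):
            ages.append("adult")
            count_a += 1
        else:
            ages.append("yearling")
    return pd.DataFrame({
        "individual_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
        "sex": sexes,
        "age": ages,
    })


@dataclass(frozen=True)
class TrajectoryTruth:
    """Generating truth for one tissue x isotope incorporation process.

    ``params`` holds the population-level curve; ``phi3_shift_by_sex`` /
    ``phi3_shift_by_age`` are additive shifts of the log-rate (a shift
    ``s`` multiplies the half-life by ``exp(-s)``); ``random_effects``
    gives the individual Gaussian SDs; ``error_sd`` is the measurement
    noise in permil.
    """

    params: OneCompartmentParams
    tissue: str = "plasma"
    isotope: str = "d13C"
    phi3_shift_by_sex: Mapping[str, float] = field(default_factory=dict)
    phi3_shift_by_age: Mapping[str, float] = field(default_factory=dict)
    random_effects: RandomEffectsSpec = field(
        default_factory=lambda: RandomEffectsSpec(("phi3",), {"phi3": 0.25}))
    error_sd: float = 0.2
    schedule: tuple[float, ...] = FULL_SCHEDULE

    def __post_init__(self) -> None:
        if self.error_sd < 0:
            raise ValueError("measurement error SD must be >= 0")
        sched = tuple(float(d) for d in self.schedule)
        if len(sched) < 2 or sched[0] != 0.0 or any(
                b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must be strictly increasing and start at day 0")
        object.__setattr__(self, "schedule", sched)


#: Generating half-lives (days) per tissue x isotope, set to the fitted
#: study estimates; initial/asymptotic values use plausible tissue
#: signatures on the terrestrial (initial) and marine (final) diets.
_DEFAULT_TRUTH_TABLE = {
    ("plasma", "d13C"): {"phi1": -17.9, "phi2": -25.2, "half_life": 9.0},
    ("plasma", "d15N"): {"phi1": 15.0, "phi2": 8.0, "half_life": 4.0},
    ("blood_cells", "d13C"): {"phi1": -18.8, "phi2": -25.4, "half_life": 43.0},
    ("blood_cells", "d15N"): {"phi1": 12.9, "phi2": 6.6, "half_life": 40.0},
}


def default_trajectory_truth(tissue: str = "plasma", isotope: str = "d13C",
                             half_life_days: float | None = None,
                             **overrides) -> TrajectoryTruth:
    """Study-calibrated generating truth for a blood tissue and isotope."""
    try:
        base = _DEFAULT_TRUTH_TABLE[(tissue, isotope)]
    except KeyError:
        raise ValueError(
            f"no default trajectory truth for tissue={tissue!r}, isotope={isotope!r}; "
            "time series exist for plasma and blood_cells only") from None
    hl = half_life_days if half_life_days is not None else base["half_life"]
    params = OneCompartmentParams(base["phi1"], base["phi2"], phi3_for_half_life(hl))
    return TrajectoryTruth(params=params, tissue=tissue, isotope=isotope, **overrides)


def _draw_individual_params(truth: TrajectoryTruth, sex: str, age: str,
                            rng: np.random.Generator) -> OneCompartmentParams:
    re = truth.random_effects
    phi1, phi2, phi3 = truth.params.phi1, truth.params.phi2, truth.params.phi3
    phi3 += truth.phi3_shift_by_sex.get(sex, 0.0)
    phi3 += truth.phi3_shift_by_age.get(age, 0.0)
    devs = {}
    for name in re.parameters_with_re:
        sd = re.sd_by_parameter.get(name, 0.0)
        devs[name] = rng.normal(0.0, sd) if sd > 0 else 0.0
    return OneCompartmentParams(phi1 + devs.get("phi1", 0.0),
                                phi2 + devs.get("phi2", 0.0),
                                phi3 + devs.get("phi3", 0.0))


def simulate_trajectories(spec: PopulationSpec, truth: TrajectoryTruth,
                          seed: int, n_dropout: int = 0,
                          dropout_days: tuple[float, ...] = (40, 41, 52, 56, 60),
                          ) -> pd.DataFrame:
    """Simulate the diet-shifted arm of the experiment.

    For each shifted individual, draws parameter deviations per the
    random-effects spec, applies sex/age shifts of the log-rate,
    evaluates the one-compartment curve at the schedule days and adds
    i.i.d. Gaussian measurement error.  Deterministic given ``seed``.

    ``n_dropout`` (off by default) emulates animals leaving the
    experiment early: the first ``n_dropout`` individuals lose all
    observations after their entry in ``dropout_days``.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for simulation")
    if n_dropout > len(dropout_days):
        raise ValueError("not enough dropout days for the requested dropouts")
    rng = np.random.default_rng(seed)
    labels = _assign_labels(spec.n_shifted, spec, prefix="fox")
    t = np.asarray(truth.schedule, dtype=float)
    records = []
    for idx, row in labels.iterrows():
        params = _draw_individual_params(truth, row["sex"], row["age"], rng)
        y = np.asarray(predict_one_compartment(params, t))
        if truth.error_sd > 0:
            y = y + rng.normal(0.0, truth.error_sd, size=len(t))
        last_day = dropout_days[idx] if idx < n_dropout else math.inf
        for ti, yi in zip(t, y):
            if ti > last_day:
                continue
            records.append({
                "individual_id": row["individual_id"], "sex": row["sex"],
                "age": row["age"], "diet": "marine", "tissue": truth.tissue,
                "isotope": truth.isotope, "day": float(ti),
                "delta_permil": float(yi),
            })
    return pd.DataFrame(records)


def simulate_control_group(spec: PopulationSpec, constant_delta: float,
                           error_sd: float, seed: int,
                           tissue: str = "plasma", isotope: str = "d13C",
                           schedule: tuple[float, ...] = FULL_SCHEDULE) -> pd.DataFrame:
    """Simulate the never-shifted control arm: flat trajectories + noise."""
    if seed is None:
        raise ValueError("a seed is mandatory for simulation")
    if error_sd < 0:
        raise ValueError("measurement error SD must be >= 0")
    rng = np.random.default_rng(seed)
    labels = _assign_labels(spec.n_control, spec, prefix="ctl")
    t = np.asarray(schedule, dtype=float)
    records = []
    for _, row in labels.iterrows():
        y = np.full(len(t), float(constant_delta))
        if error_sd > 0:
            y = y + rng.normal(0.0, error_sd, size=len(t))
        for ti, yi in zip(t, y):
            records.append({
                "individual_id": row["individual_id"], "sex": row["sex"],
                "age": row["age"], "diet": "terrestrial", "tissue": tissue,
                "isotope": isotope, "day": float(ti), "delta_permil": float(yi),
            })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Discrimination records
# ---------------------------------------------------------------------------

CellKey = tuple[str, str, str, str, str]  # (tissue, diet, sex, age, isotope)


@dataclass(frozen=True)
class DiscriminationTruth:
    """Generating truth for discrimination records.

    ``cells`` maps ``(tissue, diet, sex, age, isotope)`` to
    ``(mean, sd)`` of the discrimination in that cell; ``individual_sd``
    is the SD of a Gaussian intercept shared across all of one
    individual's tissues (individual heterogeneity).
    """

    cells: Mapping[CellKey, tuple[float, float]]
    individual_sd: float = 0.3
    diet_signatures: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_DIET_SIGNATURES.copy())

    def __post_init__(self) -> None:
        if self.individual_sd < 0:
            raise ValueError("individual intercept SD must be >= 0")
        for key, (_, sd) in self.cells.items():
            if sd < 0:
                raise ValueError(f"cell SD must be >= 0 (cell {key})")

    def cell(self, tissue: str, diet: str, sex: str, age: str,
             isotope: str) -> tuple[float, float]:
        key = (tissue, diet, sex, age, isotope)
        try:
            return self.cells[key]
        except KeyError:
            raise KeyError(
                "no generating truth for cell "
                f"(tissue={tissue}, diet={diet}, sex={sex}, age={age}, "
                f"isotope={isotope})") from None


# Sex x age discrimination cells (mean, SD, permil) on the mix diet,
# plus diet-level offsets for the blood tissues, patterned on the
# measured study values; liver cells are diet-level only.
_SEXAGE_CELLS = {
    # tissue, isotope: {(sex, age): (mean, sd)}
    ("blood_cells", "d13C"): {("F", "yearling"): (0.28, 0.16), ("F", "adult"): (0.67, 0.19),
                              ("M", "yearling"): (0.27, 0.13), ("M", "adult"): (0.57, 0.19)},
    ("plasma", "d13C"): {("F", "yearling"): (0.59, 0.25), ("F", "adult"): (0.88, 0.16),
                         ("M", "yearling"): (0.61, 0.25), ("M", "adult"): (0.80, 0.28)},
    ("muscle", "d13C"): {("F", "yearling"): (0.23, 0.60), ("F", "adult"): (0.64, 0.79),
                         ("M", "yearling"): (0.32, 0.85), ("M", "adult"): (0.31, 0.70)},
    ("fur", "d13C"): {("F", "yearling"): (1.98, 0.16), ("F", "adult"): (2.65, 0.22),
                      ("M", "yearling"): (1.89, 0.13), ("M", "adult"): (2.16, 0.32)},
    ("nail", "d13C"): {("F", "yearling"): (1.72, 0.32), ("F", "adult"): (2.94, 0.32),
                       ("M", "yearling"): (1.58, 0.41), ("M", "adult"): (2.67, 0.58)},
    ("blood_cells", "d15N"): {("F", "yearling"): (1.55, 0.82), ("F", "adult"): (2.09, 0.54),
                              ("M", "yearling"): (1.46, 0.85), ("M", "adult"): (1.93, 0.85)},
    ("plasma", "d15N"): {("F", "yearling"): (3.41, 0.28), ("F", "adult"): (3.24, 0.28),
                         ("M", "yearling"): (3.24, 0.28), ("M", "adult"): (3.08, 0.35)},
    ("muscle", "d15N"): {("F", "yearling"): (1.83, 0.76), ("F", "adult"): (1.94, 0.73),
                         ("M", "yearling"): (1.59, 0.85), ("M", "adult"): (1.92, 0.95)},
    ("fur", "d15N"): {("F", "yearling"): (2.85, 0.25), ("F", "adult"): (3.79, 0.38),
                      ("M", "yearling"): (2.77, 0.32), ("M", "adult"): (4.03, 0.54)},
    ("nail", "d15N"): {("F", "yearling"): (2.15, 0.32), ("F", "adult"): (4.70, 0.85),
                       ("M", "yearling"): (2.47, 0.38), ("M", "adult"): (5.29, 0.82)},
}

# Diet-level means for the blood tissues (mix, marine, terrestrial);
# offsets relative to the mix value are applied to every sex x age cell.
_DIET_MEANS = {
    ("blood_cells", "d13C"): {"mix": 0.49, "marine": 0.24, "terrestrial": 0.56},
    ("plasma", "d13C"): {"mix": 0.47, "marine": 1.15, "terrestrial": 0.79},
    ("blood_cells", "d15N"): {"mix": 2.56, "marine": 0.38, "terrestrial": 1.56},
    ("plasma", "d15N"): {"mix": 3.57, "marine": 2.80, "terrestrial": 3.03},
}

# Liver: diet-level cells only (small sample in the study design).
_LIVER_CELLS = {
    ("liver", "marine", "d13C"): (0.66, 0.22),
    ("liver", "terrestrial", "d13C"): (0.51, 0.22),
    ("liver", "marine", "d15N"): (1.97, 0.44),
    ("liver", "terrestrial", "d15N"): (2.68, 0.28),
}


def default_discrimination_truth(individual_sd: float = 0.3) -> DiscriminationTruth:
    """Generating truth patterned on the measured discrimination table.

    Blood cells and plasma get cells for all three diets (sex x age
    pattern shifted by diet-level offsets); muscle for the two
    post-shift diets; fur and nail for the mix diet they grew on; liver
    for marine/terrestrial without population structure.
    """
    cells: dict[CellKey, tuple[float, float]] = {}
    for (tissue, isotope), sexage in _SEXAGE_CELLS.items():
        if tissue in ("blood_cells", "plasma"):
            diets = DIETS
            diet_means = _DIET_MEANS[(tissue, isotope)]
        elif tissue == "muscle":
            diets = ("marine", "terrestrial")
            diet_means = None
        else:  # fur, nail grew on the mix diet only
            diets = ("mix",)
            diet_means = None
        for diet in diets:
            offset = (diet_means[diet] - diet_means["mix"]) if diet_means else 0.0
            for (sex, age), (mean, sd) in sexage.items():
                cells[(tissue, diet, sex, age, isotope)] = (mean + offset, sd)
    for (tissue, diet, isotope), (mean, sd) in _LIVER_CELLS.items():
        for sex in SEXES:
            for age in AGES:
                cells[(tissue, diet, sex, age, isotope)] = (mean, sd)
    return DiscriminationTruth(cells=cells, individual_sd=individual_sd)


def simulate_discrimination_dataset(truth: DiscriminationTruth,
                                    spec: PopulationSpec, seed: int,
                                    tissues: tuple[str, ...] | None = None,
                                    diets: tuple[str, ...] | None = None,
                                    isotopes: tuple[str, ...] = ISOTOPES,
                                    n_per_cell: int | None = None) -> pd.DataFrame:
    """Simulate discrimination records for a structured population.

    Each record is ``cell mean + individual intercept + residual`` with
    the intercept shared across one individual's tissues and isotopes.
    When ``n_per_cell`` is given, that many individuals are generated
    for every sex x age cell instead of the spec's population.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for simulation")
    rng = np.random.default_rng(seed)
    if n_per_cell is not None:
        rows = []
        i = 0
        for sex in SEXES:
            for age in AGES:
                for _ in range(n_per_cell):
                    rows.append({"individual_id": f"fox{i + 1:05d}",
                                 "sex": sex, "age": age})
                    i += 1
        labels = pd.DataFrame(rows)
    else:
        labels = _assign_labels(spec.n_individuals, spec, prefix="fox")

    # When tissues/diets are requested explicitly, every requested cell
    # must have a truth entry; by default the observed combinations in
    # the truth table define the layout.
    strict = tissues is not None and diets is not None
    observed = {(t, d) for (t, d, _, _, _) in truth.cells}
    if tissues is None:
        tissues = tuple(sorted({t for t, _ in observed}, key=TISSUES.index))
    if diets is None:
        diets = tuple(sorted({d for _, d in observed}, key=DIETS.index))
    combos = [(t, d) for t in tissues for d in diets
              if strict or (t, d) in observed]

    records = []
    for _, row in labels.iterrows():
        intercept = (rng.normal(0.0, truth.individual_sd)
                     if truth.individual_sd > 0 else 0.0)
        for tissue, diet in combos:
            for isotope in isotopes:
                mean, sd = truth.cell(tissue, diet, row["sex"],
                                      row["age"], isotope)
                value = mean + intercept
                if sd > 0:
                    value += rng.normal(0.0, sd)
                records.append({
                    "individual_id": row["individual_id"],
                    "sex": row["sex"], "age": row["age"],
                    "tissue": tissue, "diet": diet, "isotope": isotope,
                    "discrimination_permil": float(value),
                    "lipid_corrected": isotope == "d13C",
                })
    if not records:
        raise KeyError("no generating truth for any requested cell; check the "
                       "tissue/diet/isotope combinations")
    return pd.DataFrame(records)
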