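"""Egg-volume features and nest-level predictor tables.

Turns raw nest records (per-egg length/width) and the annual environment
table into the predictor matrix the age models consume: per-nest total and
mean egg volume (VT, VM), clutch size, year, and the annual covariates
(Food, z-scored food per capita, NAO indices, population sizes), plus the
age-class label under one of four pooling schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MAX_CLUTCH, VOLUME_COEF

__all__ = [
    "AgeClassScheme",
    "SCHEMES",
    "MODEL_VERSIONS",
    "egg_volume",
    "nest_features",
    "food_per_capita",
    "z_transform",
    "age_to_class",
    "prepare_environment",
    "build_feature_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeClassScheme:
    """An ordered partition of ages [3, inf) into labelled classes.

    ``breaks`` is a tuple of (lo, hi, label); hi is inclusive, None meaning
    open-ended.  Ranges must tile [3, inf) without gaps or overlap.
    """

    name: str
    breaks: tuple[tuple[int, int | None, str], ...]

    def __post_init__(self) -> None:
        lo0 = self.breaks[0][0]
        if lo0 != 3:
            raise ValueError("schemes must start at age 3 (sexual maturity)")
        prev_hi = lo0 - 1
        for lo, hi, _label in self.breaks[:-1]:
            if lo != prev_hi + 1 or hi is None or hi < lo:
                raise ValueError(f"scheme {self.name}: ranges must tile [3, inf)")
            prev_hi = hi
        last_lo, last_hi, _ = self.breaks[-1]
        if last_lo != prev_hi + 1 or last_hi is not None:
            raise ValueError(f"scheme {self.name}: final range must be open-ended")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, _, label in self.breaks)

    @property
    def n_classes(self) -> int:
        return len(self.breaks)


def _singles(lo: int, hi: int) -> tuple[tuple[int, int, str], ...]:
    return tuple((a, a, str(a)) for a in range(lo, hi + 1))


#: The four age-class pooling schemes used by the classification models:
#: AGE14 — ages 3..15 each their own class, 16+ pooled 'Old';
#: AGE6  — 3,4,5,6 separate, 7–15 'Middle-aged', 16+ 'Old';
#: AGE3  — 3–4 'Young', 5–15 'Middle-aged', 16+ 'Old';
#: AGE2  — 3–4 'Young', 5+ 'Others'.
SCHEMES: dict[str, AgeClassScheme] = {
    "AGE14": AgeClassScheme("AGE14", _singles(3, 15) + ((16, None, "Old"),)),
    "AGE6": AgeClassScheme(
        "AGE6", _singles(3, 6) + ((7, 15, "Middle-aged"), (16, None, "Old"))
    ),
    "AGE3": AgeClassScheme(
        "AGE3", ((3, 4, "Young"), (5, 15, "Middle-aged"), (16, None, "Old"))
    ),
    "AGE2": AgeClassScheme("AGE2", ((3, 4, "Young"), (5, None, "Others"))),
}

#: Predictor column sets for the model versions (Table-style variable subsets).
MODEL_VERSIONS: dict[str, tuple[str, ...]] = {
    "full": (
        "VM", "VT", "Clutch", "Year",
        "Food", "Foodpc", "La_Popsize", "Popsize", "WNAO", "ANAO",
    ),
    "M4.1": (
        "VM", "VT", "Clutch", "Year",
        "Food", "Foodpc", "La_Popsize", "Popsize", "WNAO", "ANAO",
    ),
    "M4.2": (
        "VM", "VT", "Clutch",
        "Food", "Foodpc", "La_Popsize", "Popsize", "WNAO", "ANAO",
    ),
    "M4.3": ("VM", "VT", "Clutch", "Year"),
    "M4.4": ("VM", "VT", "Clutch"),
}


def egg_volume(length: float, width: float) -> float:
    """Egg volume in cm^3 from length and width in mm: 0.000476 * L * W^2."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("egg dimensions must be positive")
    out = VOLUME_COEF * length * width**2
    return float(out) if out.ndim == 0 else out


def nest_features(eggs: list[tuple[float, float]]) -> tuple[float, float, int]:
    """Per-nest aggregates from (length_mm, width_mm) pairs: (VT, VM, clutch)."""
    if not eggs:
        raise ValueError("nest has no measured eggs")
    volumes = [egg_volume(length, width) for length, width in eggs]
    vt = float(np.sum(volumes))
    clutch = len(volumes)
    return vt, vt / clutch, clutch


def food_per_capita(food: float, la_popsize: float, popsize: float) -> float:
    """Fish landings divided by the combined breeding population of both gull species."""
    if popsize <= 0:
        raise ValueError("popsize must be positive")
    if la_popsize > popsize:
        raise ValueError("la_popsize cannot exceed total popsize")
    return food / popsize


def z_transform(values, name: str = "series") -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"{name}: need at least 2 values to z-transform")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name}: zero variance, cannot z-transform")
    return (x - x.mean()) / sd


def age_to_class(age: int, scheme: AgeClassScheme) -> str:
    """Map an age in years to its class label under ``scheme``."""
    if age < 3:
        raise ValueError(f"age {age} below age at maturity (3)")
    for lo, hi, label in scheme.breaks:
        if age >= lo and (hi is None or age <= hi):
            return label
    raise AssertionError("unreachable: schemes tile [3, inf)")


def prepare_environment(environment: pd.DataFrame) -> pd.DataFrame:
    """Add Foodpc (z-scored food per capita) to the annual table.

    The z-scoring is done once over all years of the table; subsets of nests
    later inherit these values rather than being re-standardized.
    """
    env = environment.copy()
    fpc = np.array(
        [
            food_per_capita(f, la, p)
            for f, la, p in zip(env["food"], env["la_popsize"], env["popsize"])
        ]
    )
    env["foodpc"] = z_transform(fpc, name="foodpc")
    return env


def _egg_pairs(row: pd.Series) -> list[tuple[float, float]] | None:
    eggs = []
    for i in range(1, MAX_CLUTCH + 1):
        length = row.get(f"egg{i}_length_mm")
        width = row.get(f"egg{i}_width_mm")
        if pd.isna(length) and pd.isna(width):
            continue
        if pd.isna(length) or pd.isna(width):
            return None  # half-measured egg
        eggs.append((float(length), float(width)))
    if len(eggs) != int(row["clutch"]):
        return None
    return eggs


def build_feature_table(
    nests: pd.DataFrame,
    environment: pd.DataFrame | None,
    version: str = "full",
    scheme: AgeClassScheme | str | None = None,
) -> pd.DataFrame:
    """Assemble the nest-level predictor table for one model version.

    Joins per-nest egg aggregates with the annual covariates and, if a
    scheme is given, labels each known-age nest with its age class.  Nests
    with missing or inconsistent egg measurements are dropped with a logged
    count.  ``environment`` may be None only for the egg-only versions
    (M4.3 without env covariates still needs Year from the nest table).
    """
    if version not in MODEL_VERSIONS:
        raise ValueError(f"unknown model version {version!r}; use {sorted(MODEL_VERSIONS)}")
    predictors = MODEL_VERSIONS[version]
    needs_env = any(
        c in predictors for c in ("Food", "Foodpc", "La_Popsize", "Popsize", "WNAO", "ANAO")
    )
    if needs_env and environment is None:
        raise ValueError(f"version {version} requires the environment table")
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]

    if needs_env:
        env = prepare_environment(environment)
        missing = sorted(set(nests["year"]) - set(env["year"]))
        if missing:
            raise ValueError(f"nest years missing from environment table: {missing}")

    rows = []
    n_dropped = 0
    for _, nest in nests.iterrows():
        eggs = _egg_pairs(nest)
        if eggs is None:
            n_dropped += 1
            continue
        vt, vm, clutch = nest_features(eggs)
        row = {
            "nest_id": nest["nest_id"],
            "VT": vt,
            "VM": vm,
            "Clutch": clutch,
            "Year": int(nest["year"]),
        }
        if "colony" in nest.index:
            row["colony"] = nest["colony"]
        if not pd.isna(nest.get("age")):
            row["age"] = int(nest["age"])
            if scheme is not None:
                row["age_class"] = age_to_class(int(nest["age"]), scheme)
        rows.append(row)
    if n_dropped:
        logger.info("dropped %d nests with missing/inconsistent egg measurements", n_dropped)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no usable nests after dropping incomplete records")

    if needs_env:
        env_cols = env.rename(
            columns={
                "anao": "ANAO",
                "wnao": "WNAO",
                "food": "Food",
                "foodpc": "Foodpc",
                "la_popsize": "La_Popsize",
                "popsize": "Popsize",
            }
        )
        table = table.merge(env_cols.rename(columns={"year": "Year"}), on="Year", how="left")

    keep = [c for c in ("nest_id", "colony", "age", "age_class") if c in table.columns]
    table = table[keep + list(predictors)]
    table.attrs["version"] = version
    table.attrs["predictors"] = list(predictors)
    if scheme is not None:
        table.attrs["scheme"] = scheme.name
    return table
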