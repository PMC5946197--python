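"""Derived adiposity and haemodynamic indices.

Cubic mass indices divide mass by height cubed, which (unlike BMI's square
exponent) is approximately size-invariant during growth:

* BMI  = weight / height^2          [kg/m^2]
* TMI  = weight / height^3          [kg/m^3]   (tri-ponderal mass index)
* FMI  = fat mass / height^3        [kg fat/m^3]  (cubic fat mass index)

Fat mass is body-fat percent times body weight.  Mean arterial pressure is
either the physiological estimate DBP + (SBP - DBP)/3 ("standard") or the
arithmetic mean of SBP and DBP.  An LMS z-score against any user-supplied
growth-reference table (e.g. a WHO 2007 extract) is also provided.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .cohort import Cohort, Sex, DEFAULT_SEX_CODES
from .errors import CoverageError, DomainError

MapFormula = Literal["standard", "arithmetic_mean"]

#: derived-index column names appended by :func:`add_indices`
INDEX_COLUMNS = ("bmi", "tmi", "fat_mass", "fmi", "map")


def _check_positive(name: str, value) -> None:
    if np.any(np.asarray(value, dtype=float) <= 0):
        raise DomainError(f"{name} must be > 0")


def compute_bmi(weight, height):
    """Body mass index, weight (kg) / height (m) squared."""
    _check_positive("weight", weight)
    _check_positive("height", height)
    return np.asarray(weight, dtype=float) / np.asarray(height, dtype=float) ** 2


def compute_tmi(weight, height):
    """Tri-ponderal mass index, weight (kg) / height (m) cubed."""
    _check_positive("weight", weight)
    _check_positive("height", height)
    return np.asarray(weight, dtype=float) / np.asarray(height, dtype=float) ** 3


def compute_fat_mass(body_fat_pct, weight):
    """Fat mass in kg from body-fat percent and body weight."""
    bf = np.asarray(body_fat_pct, dtype=float)
    if np.any(bf < 0) or np.any(bf >= 100):
        raise DomainError("body_fat_pct must lie in [0, 100)")
    _check_positive("weight", weight)
    return bf / 100.0 * np.asarray(weight, dtype=float)


def compute_fmi(fat_mass, height):
    """Cubic fat mass index, fat mass (kg) / height (m) cubed."""
    if np.any(np.asarray(fat_mass, dtype=float) < 0):
        raise DomainError("fat_mass must be >= 0")
    _check_positive("height", height)
    return np.asarray(fat_mass, dtype=float) / np.asarray(height, dtype=float) ** 3


def compute_map(sbp, dbp, formula: MapFormula = "standard"):
    """Mean arterial pressure in mmHg.

    ``standard``        DBP + (SBP - DBP) / 3  (diastole-weighted estimate)
    ``arithmetic_mean`` (SBP + DBP) / 2
    """
    s = np.asarray(sbp, dtype=float)
    d = np.asarray(dbp, dtype=float)
    _check_positive("dbp", d)
    if np.any(s <= d):
        raise DomainError("sbp must exceed dbp")
    if formula == "standard":
        return d + (s - d) / 3.0
    if formula == "arithmetic_mean":
        return (s + d) / 2.0
    raise DomainError(f"unknown MAP formula {formula!r}")


class LmsReferenceTable:
    """Sex- and age-keyed LMS (lambda-mu-sigma) growth reference.

    Expects columns ``sex`` (female/male or F/M codes), ``age`` (years),
    ``L`` (Box-Cox power), ``M`` (median, > 0) and ``S`` (coefficient of
    variation, > 0); ages must be strictly increasing within each sex.
    L, M and S are linearly interpolated between tabulated ages; ages
    outside the tabulated range raise :class:`CoverageError` rather than
    extrapolating.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        required = {"sex", "age", "L", "M", "S"}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"LMS table lacks column(s): {sorted(missing)}")
        df["sex"] = [
            DEFAULT_SEX_CODES[str(s).strip().lower()].value for s in df["sex"]
        ]
        for sex, grp in df.groupby("sex"):
            ages = grp["age"].to_numpy(dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise DomainError(f"LMS ages must be strictly increasing ({sex})")
        if np.any(df["M"].to_numpy(dtype=float) <= 0):
            raise DomainError("LMS M values must be > 0")
        if np.any(df["S"].to_numpy(dtype=float) <= 0):
            raise DomainError("LMS S values must be > 0")
        self.table = df

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "LmsReferenceTable":
        return cls(pd.read_csv(path, sep=sep))

    def lookup(self, sex: Sex | str, age: float) -> tuple[float, float, float]:
        sex_value = sex.value if isinstance(sex, Sex) else Sex(sex).value
        grp = self.table[self.table["sex"] == sex_value]
        if grp.empty:
            raise CoverageError(f"no LMS rows for sex {sex_value!r}")
        ages = grp["age"].to_numpy(dtype=float)
        if age < ages[0] or age > ages[-1]:
            raise CoverageError(
                f"age {age} outside LMS coverage [{ages[0]}, {ages[-1]}] for {sex_value}"
            )
        L = float(np.interp(age, ages, grp["L"].to_numpy(dtype=float)))
        M = float(np.interp(age, ages, grp["M"].to_numpy(dtype=float)))
        S = float(np.interp(age, ages, grp["S"].to_numpy(dtype=float)))
        return L, M, S

    def zscore(self, value: float, sex: Sex | str, age: float) -> float:
        if value <= 0:
            raise DomainError("value must be > 0 for an LMS z-score")
        L, M, S = self.lookup(sex, age)
        if abs(L) < 1e-12:
            return float(np.log(value / M) / S)
        return float(((value / M) ** L - 1.0) / (L * S))


def compute_lms_z(value, sex, age, ref: LmsReferenceTable) -> float:
    """LMS z-score of ``value`` against a growth reference table."""
    return ref.zscore(value, sex, age)


def add_indices(
    data: Cohort | pd.DataFrame,
    map_formula: MapFormula = "standard",
    lms: LmsReferenceTable | None = None,
) -> pd.DataFrame:
    """Return a copy of the cohort table with derived-index columns appended.

    Appends ``bmi``, ``tmi``, ``fat_mass``, ``fmi`` and ``map``; when an LMS
    reference is supplied, also ``bmi_z`` (NaN where the reference does not
    cover the subject's age).
    """
    df = (data.data if isinstance(data, Cohort) else data).copy()
    df["bmi"] = compute_bmi(df["weight"], df["height"])
    df["tmi"] = compute_tmi(df["weight"], df["height"])
    df["fat_mass"] = compute_fat_mass(df["body_fat_pct"], df["weight"])
    df["fmi"] = compute_fmi(df["fat_mass"], df["height"])
    df["map"] = compute_map(df["sbp"], df["dbp"], formula=map_formula)
    if lms is not None:
        zs = []
        for bmi, sex, age in zip(df["bmi"], df["sex"], df["age"]):
            try:
                zs.append(lms.zscore(float(bmi), sex, float(age)))
            except CoverageError:
                zs.append(np.nan)
        df["bmi_z"] = zs
    return df
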