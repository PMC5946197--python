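"""Rule-based metabolic-syndrome classification and the continuous score.

MetS is the co-occurrence of at least ``min_components`` (default 3) of
five abnormalities: abdominal obesity, high triglycerides, low HDL-C,
elevated blood pressure, elevated fasting glucose.  Two criterion sets are
built in:

* an adult set with harmonized IDF thresholds (WC >= 80 cm women / 90 cm
  men; TG >= 150 mg/dL; HDL < 50 women / 40 men; SBP >= 130 or DBP >= 85
  mmHg; glucose >= 100 mg/dL), and
* a paediatric, de Ferranti-style set (TG >= 100 mg/dL; HDL < 50 mg/dL,
  < 45 for boys aged >= 15; WC above the sex-specific 75th percentile;
  SBP or DBP above the age/sex 90th percentile; glucose >= 110 mg/dL),
  whose percentile lookups are user-supplied tables (or derived
  empirically from a cohort).

The continuous MetS score standardizes each risk component over the whole
analyzed cohort (z-scores; HDL negated so higher is always worse) and
aggregates them, so the cohort mean is zero by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import AgeGroup, Cohort, Sex, DEFAULT_SEX_CODES, YOUNG_ADULTS
from .errors import (
    ClassificationError,
    CriteriaConstructionError,
    DegenerateCohortError,
)

COMPONENTS = (
    "abdominal_obesity",
    "triglycerides",
    "hdl",
    "blood_pressure",
    "glucose",
)


@dataclass(frozen=True)
class ComponentRule:
    """Deterministic abnormality predicate for one MetS component."""

    component: str
    description: str
    required_fields: tuple[str, ...]
    predicate: Callable[[Mapping], bool]

    def __call__(self, row: Mapping) -> bool:
        for f in self.required_fields:
            v = row.get(f) if hasattr(row, "get") else row[f]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ClassificationError(
                    f"component {self.component!r} requires field {f!r}, "
                    f"missing for subject {row.get('id', '?')!r}"
                )
        return bool(self.predicate(row))


@dataclass(frozen=True)
class CriterionSet:
    """Named set of five component rules plus the counting rule.

    ``mandatory`` optionally names a component that must itself be abnormal
    for a MetS call (canonical IDF makes central obesity mandatory); the
    default follows the uniform >= ``min_components`` counting rule.
    """

    name: str
    rules: tuple[ComponentRule, ...]
    min_components: int = 3
    mandatory: str | None = None

    def __post_init__(self):
        got = tuple(r.component for r in self.rules)
        if got != COMPONENTS:
            raise CriteriaConstructionError(
                f"criterion set needs one rule per component {COMPONENTS}, got {got}"
            )
        if not 1 <= self.min_components <= 5:
            raise CriteriaConstructionError("min_components must be in 1..5")
        if self.mandatory is not None and self.mandatory not in COMPONENTS:
            raise CriteriaConstructionError(
                f"unknown mandatory component {self.mandatory!r}"
            )


@dataclass(frozen=True)
class MetSResult:
    component_flags: dict
    n_abnormal: int
    mets: bool


def classify_mets(row: Mapping, criteria: CriterionSet) -> MetSResult:
    """Evaluate each component rule independently and apply the count rule."""
    flags = {r.component: r(row) for r in criteria.rules}
    n = sum(flags.values())
    mets = n >= criteria.min_components
    if criteria.mandatory is not None:
        mets = mets and flags[criteria.mandatory]
    return MetSResult(component_flags=flags, n_abnormal=n, mets=mets)


def _sex_of(row: Mapping) -> Sex:
    return DEFAULT_SEX_CODES[str(row["sex"]).strip().lower()]


def idf_adult_criteria(
    min_components: int = 3, mandatory: str | None = None
) -> CriterionSet:
    """Harmonized IDF adult thresholds with a uniform counting rule."""
    rules = (
        ComponentRule(
            "abdominal_obesity",
            "WC >= 80 cm (women) / 90 cm (men)",
            ("waist", "sex"),
            lambda r: r["waist"] >= (80.0 if _sex_of(r) is Sex.FEMALE else 90.0),
        ),
        ComponentRule(
            "triglycerides",
            "TG >= 150 mg/dL",
            ("triglycerides",),
            lambda r: r["triglycerides"] >= 150.0,
        ),
        ComponentRule(
            "hdl",
            "HDL-C < 50 mg/dL (women) / 40 mg/dL (men)",
            ("hdl", "sex"),
            lambda r: r["hdl"] < (50.0 if _sex_of(r) is Sex.FEMALE else 40.0),
        ),
        ComponentRule(
            "blood_pressure",
            "SBP >= 130 or DBP >= 85 mmHg",
            ("sbp", "dbp"),
            lambda r: r["sbp"] >= 130.0 or r["dbp"] >= 85.0,
        ),
        ComponentRule(
            "glucose",
            "fasting glucose >= 100 mg/dL",
            ("glucose",),
            lambda r: r["glucose"] >= 100.0,
        ),
    )
    return CriterionSet("IDF-adult", rules, min_components, mandatory)


class PercentileTable:
    """Sex x integer-age lookup of one percentile value.

    Lookup uses the nearest tabulated integer age within the subject's sex
    (paediatric references tabulate whole years); ties round down.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age", "value"}
        missing = required - set(table.columns)
        if missing:
            raise CriteriaConstructionError(
                f"percentile table lacks column(s): {sorted(missing)}"
            )
        df = table.copy()
        df["sex"] = [
            DEFAULT_SEX_CODES[str(s).strip().lower()].value for s in df["sex"]
        ]
        df["age"] = df["age"].astype(int)
        self._by_sex = {
            sex: grp.sort_values("age").set_index("age")["value"]
            for sex, grp in df.groupby("sex")
        }

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "PercentileTable":
        return cls(pd.read_csv(path, sep=sep))

    @classmethod
    def from_cohort(
        cls, df: pd.DataFrame, column: str, q: float
    ) -> "PercentileTable":
        """Empirical per-(sex, whole-year age) quantile of ``column``."""
        tmp = df.assign(_age=np.floor(df["age"]).astype(int))
        out = (
            tmp.groupby(["sex", "_age"])[column]
            .quantile(q)
            .reset_index()
            .rename(columns={"_age": "age", column: "value"})
        )
        return cls(out)

    def lookup(self, sex: Sex | str, age: float) -> float:
        sex_value = sex.value if isinstance(sex, Sex) else Sex(sex).value
        series = self._by_sex.get(sex_value)
        if series is None or series.empty:
            raise CriteriaConstructionError(
                f"percentile table has no rows for sex {sex_value!r}"
            )
        ages = series.index.to_numpy()
        nearest = ages[np.argmin(np.abs(ages - age))]
        return float(series.loc[nearest])


@dataclass(frozen=True)
class PediatricPercentileTables:
    """Percentile lookups required by the paediatric criterion set."""

    wc_p75: PercentileTable
    sbp_p90: PercentileTable
    dbp_p90: PercentileTable

    @classmethod
    def from_cohort(cls, df: pd.DataFrame) -> "PediatricPercentileTables":
        return cls(
            wc_p75=PercentileTable.from_cohort(df, "waist", 0.75),
            sbp_p90=PercentileTable.from_cohort(df, "sbp", 0.90),
            dbp_p90=PercentileTable.from_cohort(df, "dbp", 0.90),
        )


def pediatric_criteria(
    tables: PediatricPercentileTables | None,
    min_components: int = 3,
    mandatory: str | None = None,
) -> CriterionSet:
    """de Ferranti-style paediatric thresholds with percentile lookups."""
    if tables is None:
        raise CriteriaConstructionError(
            "paediatric criteria require percentile tables: "
            "wc_p75, sbp_p90, dbp_p90 (see PediatricPercentileTables)"
        )

    def low_hdl(r: Mapping) -> bool:
        cut = 45.0 if (_sex_of(r) is Sex.MALE and r["age"] >= 15.0) else 50.0
        return r["hdl"] < cut

    rules = (
        ComponentRule(
            "abdominal_obesity",
            "WC > sex-specific 75th percentile",
            ("waist", "sex", "age"),
            lambda r: r["waist"] > tables.wc_p75.lookup(r["sex"], r["age"]),
        ),
        ComponentRule(
            "triglycerides",
            "TG >= 100 mg/dL",
            ("triglycerides",),
            lambda r: r["triglycerides"] >= 100.0,
        ),
        ComponentRule(
            "hdl",
            "HDL-C < 50 mg/dL (< 45 for boys >= 15 y)",
            ("hdl", "sex", "age"),
            low_hdl,
        ),
        ComponentRule(
            "blood_pressure",
            "SBP or DBP > age/sex 90th percentile",
            ("sbp", "dbp", "sex", "age"),
            lambda r: r["sbp"] > tables.sbp_p90.lookup(r["sex"], r["age"])
            or r["dbp"] > tables.dbp_p90.lookup(r["sex"], r["age"]),
        ),
        ComponentRule(
            "glucose",
            "fasting glucose >= 110 mg/dL",
            ("glucose",),
            lambda r: r["glucose"] >= 110.0,
        ),
    )
    return CriterionSet("deFerranti-pediatric", rules, min_components, mandatory)


def build_default_criteria(
    age_group: AgeGroup,
    percentile_tables: PediatricPercentileTables | None = None,
    min_components: int = 3,
    mandatory: str | None = None,
) -> CriterionSet:
    """IDF-adult set for young adults, paediatric set otherwise."""
    if age_group.label == YOUNG_ADULTS.label:
        return idf_adult_criteria(min_components, mandatory)
    return pediatric_criteria(percentile_tables, min_components, mandatory)


def classify_cohort(
    data: Cohort | pd.DataFrame,
    percentile_tables: PediatricPercentileTables | None = None,
    age_groups: Sequence[AgeGroup] | None = None,
    min_components: int = 3,
    mandatory: str | None = None,
) -> pd.DataFrame:
    """Classify every subject under the age-group-appropriate criterion set.

    Returns a copy of the table with one boolean column per component
    (``flag_<component>``), ``n_abnormal`` and ``mets``.  Requires an
    ``age_group`` column (see :func:`metscreen.cohort.assign_age_group`).
    """
    from .cohort import DEFAULT_AGE_GROUPS, assign_age_group

    df = (data.data if isinstance(data, Cohort) else data).copy()
    groups = tuple(age_groups or DEFAULT_AGE_GROUPS)
    if "age_group" not in df.columns:
        df["age_group"] = [assign_age_group(a, groups).label for a in df["age"]]
    by_label = {g.label: g for g in groups}
    criteria_cache: dict[str, CriterionSet] = {}
    flags = {c: np.zeros(len(df), dtype=bool) for c in COMPONENTS}
    n_abn = np.zeros(len(df), dtype=int)
    mets = np.zeros(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        label = row["age_group"]
        if label not in criteria_cache:
            criteria_cache[label] = build_default_criteria(
                by_label[label], percentile_tables, min_components, mandatory
            )
        res = classify_mets(row, criteria_cache[label])
        for c in COMPONENTS:
            flags[c][i] = res.component_flags[c]
        n_abn[i] = res.n_abnormal
        mets[i] = res.mets
    for c in COMPONENTS:
        df[f"flag_{c}"] = flags[c]
    df["n_abnormal"] = n_abn
    df["mets"] = mets
    return df


@dataclass(frozen=True)
class ContinuousScoreSpec:
    """Composition of the continuous MetS score.

    ``components`` are (column, sign) pairs; HDL enters negated so that
    larger scores always mean worse risk.  Standardization always uses the
    analyzed table's own mean and SD ("total cohort" scope).
    """

    components: tuple[tuple[str, int], ...] = (
        ("waist", 1),
        ("map", 1),
        ("triglycerides", 1),
        ("hdl", -1),
        ("glucose", 1),
    )
    aggregation: Literal["mean", "sum"] = "mean"


DEFAULT_SCORE_SPEC = ContinuousScoreSpec()


def continuous_mets_score(
    data: Cohort | pd.DataFrame, spec: ContinuousScoreSpec = DEFAULT_SCORE_SPEC
) -> pd.Series:
    """Cohort-standardized continuous MetS score (mean zero by construction).

    Each component is z-scored over the table (sample SD), multiplied by its
    sign, and aggregated per ``spec``.  Raises
    :class:`DegenerateCohortError` for n < 2 or a zero-variance component.
    """
    df = data.data if isinstance(data, Cohort) else data
    if len(df) < 2:
        raise DegenerateCohortError("continuous score needs at least 2 subjects")
    zs = []
    for col, sign in spec.components:
        if col not in df.columns:
            raise DegenerateCohortError(
                f"score component {col!r} missing; derive indices first"
            )
        x = df[col].to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateCohortError(f"component {col!r} has zero variance")
        zs.append(sign * (x - x.mean()) / sd)
    stacked = np.vstack(zs)
    agg = stacked.mean(axis=0) if spec.aggregation == "mean" else stacked.sum(axis=0)
    return pd.Series(agg, index=df.index, name="mets_score")
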