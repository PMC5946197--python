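"""Cohort domain types, delimited-text I/O, and validation.

A cohort is one row per subject with anthropometry (weight in kg, height in
m, waist circumference in cm, body-fat percent from bioimpedance), blood
pressure (mmHg), and fasting biomarkers (mg/dL).  Records failing validation
are quarantined into a rejection log rather than silently dropped, so
``accepted + rejected == total rows`` always holds.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AgeOutOfRangeError, SchemaError


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


#: canonical numeric column names, in canonical order
NUMERIC_COLUMNS: tuple[str, ...] = (
    "age",
    "weight",
    "height",
    "waist",
    "body_fat_pct",
    "sbp",
    "dbp",
    "triglycerides",
    "hdl",
    "ldl",
    "total_cholesterol",
    "glucose",
)

COLUMNS: tuple[str, ...] = ("id", "sex") + NUMERIC_COLUMNS

#: admissible age window in years (half-open)
DEFAULT_AGE_WINDOW: tuple[float, float] = (9.0, 26.0)

#: accepted sex codes (case-insensitive) -> canonical sex
DEFAULT_SEX_CODES: dict[str, Sex] = {
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
}

#: heights above this are assumed to be centimetres and divided by 100
CM_HEIGHT_THRESHOLD = 3.0


@dataclass(frozen=True)
class AgeGroup:
    """Half-open age bin ``[lower, upper)`` in years."""

    label: str
    lower: float
    upper: float

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.upper

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


CHILDREN = AgeGroup("children", 9.0, 13.0)
ADOLESCENTS = AgeGroup("adolescents", 13.0, 18.0)
YOUNG_ADULTS = AgeGroup("young_adults", 18.0, 26.0)

DEFAULT_AGE_GROUPS: tuple[AgeGroup, ...] = (CHILDREN, ADOLESCENTS, YOUNG_ADULTS)


def assign_age_group(
    age: float, bins: Sequence[AgeGroup] = DEFAULT_AGE_GROUPS
) -> AgeGroup:
    """Return the unique bin whose half-open interval contains ``age``.

    Raises :class:`AgeOutOfRangeError` when the age lies outside every bin.
    """
    for b in bins:
        if b.contains(age):
            return b
    lo = min(b.lower for b in bins)
    hi = max(b.upper for b in bins)
    raise AgeOutOfRangeError(
        f"age {age!r} outside admissible window [{lo}, {hi})"
    )


@dataclass
class SubjectRecord:
    """One participant's raw measurements.

    Units: weight kg, height m, waist cm, blood pressure mmHg, body fat as a
    percent of body weight, biomarkers mg/dL.
    """

    id: str
    sex: Sex
    age: float
    weight: float
    height: float
    waist: float
    body_fat_pct: float
    sbp: float
    dbp: float
    triglycerides: float
    hdl: float
    ldl: float
    total_cholesterol: float
    glucose: float

    def validation_errors(
        self, age_window: tuple[float, float] = DEFAULT_AGE_WINDOW
    ) -> list[tuple[str, str]]:
        """Return ``(field, reason)`` pairs; empty list means valid."""
        errs: list[tuple[str, str]] = []
        for name in NUMERIC_COLUMNS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                errs.append((name, "missing"))
        if errs:
            return errs
        if not (age_window[0] <= self.age < age_window[1]):
            errs.append(
                ("age", f"outside admissible window [{age_window[0]}, {age_window[1]})")
            )
        if self.weight <= 0:
            errs.append(("weight", "must be > 0"))
        if self.height <= 0:
            errs.append(("height", "must be > 0"))
        if self.waist <= 0:
            errs.append(("waist", "must be > 0"))
        if not (0 <= self.body_fat_pct < 100):
            errs.append(("body_fat_pct", "must lie in [0, 100)"))
        if self.dbp <= 0:
            errs.append(("dbp", "must be > 0"))
        elif self.sbp <= self.dbp:
            errs.append(("sbp", "must exceed dbp"))
        for name in ("triglycerides", "hdl", "ldl", "total_cholesterol", "glucose"):
            if getattr(self, name) <= 0:
                errs.append((name, "must be > 0"))
        return errs


def _empty_rejections() -> pd.DataFrame:
    return pd.DataFrame(columns=["row", "field", "reason"])


@dataclass
class Cohort:
    """Validated cohort table plus quarantine log.

    ``data`` holds the canonical columns (see :data:`COLUMNS`); extra columns
    (e.g. ``age_group`` tags added by the simulator) are preserved.
    ``rejections`` has columns ``row`` (1-based data row in the source),
    ``field`` and ``reason``.
    """

    data: pd.DataFrame
    provenance: str = ""
    rejections: pd.DataFrame = field(default_factory=_empty_rejections)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self) -> list[SubjectRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            out.append(
                SubjectRecord(
                    id=str(d["id"]),
                    sex=Sex(d["sex"]),
                    **{k: float(d[k]) for k in NUMERIC_COLUMNS},
                )
            )
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[SubjectRecord], provenance: str = ""
    ) -> "Cohort":
        rows = []
        for r in records:
            d = {"id": r.id, "sex": r.sex.value}
            d.update({k: getattr(r, k) for k in NUMERIC_COLUMNS})
            rows.append(d)
        return cls(pd.DataFrame(rows, columns=list(COLUMNS)), provenance)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
    sex_codes: Mapping[str, Sex] | None = None,
    convert_height_cm: bool = True,
    age_window: tuple[float, float] = DEFAULT_AGE_WINDOW,
) -> Cohort:
    """Read a delimited cohort table with validation and a rejection log.

    Parameters
    ----------
    path
        Delimited text file with a header row, one subject per row.
    schema
        Mapping from canonical column names (:data:`COLUMNS`) to the file's
        column names.  Defaults to the identity mapping.
    sep
        Field delimiter; ``None`` sniffs comma/tab.
    sex_codes
        Case-insensitive mapping from sex codes to :class:`Sex`; unknown
        codes reject the row (never guessed).
    convert_height_cm
        When true, heights above :data:`CM_HEIGHT_THRESHOLD` metres are
        interpreted as centimetres and divided by 100.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file does not exist: {path}")
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype=str)
    schema = dict(schema) if schema else {c: c for c in COLUMNS}
    for canonical in COLUMNS:
        schema.setdefault(canonical, canonical)
    missing = [schema[c] for c in COLUMNS if schema[c] not in raw.columns]
    if missing:
        raise SchemaError(f"input header lacks mapped column(s): {', '.join(missing)}")
    codes = {
        k.lower(): v for k, v in (sex_codes or DEFAULT_SEX_CODES).items()
    }

    accepted: list[dict] = []
    rejected: list[dict] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        src = dict(zip(raw.columns, row))
        errs: list[tuple[str, str]] = []
        rid = str(src[schema["id"]]).strip()
        sex_raw = str(src[schema["sex"]]).strip().lower()
        sex = codes.get(sex_raw)
        if sex is None:
            errs.append(("sex", f"unknown sex code {src[schema['sex']]!r}"))
        vals: dict[str, float] = {}
        for name in NUMERIC_COLUMNS:
            cell = src[schema[name]]
            try:
                vals[name] = float(cell)
            except (TypeError, ValueError):
                vals[name] = math.nan
                errs.append((name, f"unparseable value {cell!r}"))
        if convert_height_cm and vals.get("height", 0) > CM_HEIGHT_THRESHOLD:
            vals["height"] = vals["height"] / 100.0
        if not errs:
            rec = SubjectRecord(id=rid, sex=sex, **vals)
            errs = rec.validation_errors(age_window)
            if not errs and rid in seen_ids:
                errs = [("id", f"duplicate id {rid!r}")]
        if errs:
            for fieldname, reason in errs:
                rejected.append({"row": i, "field": fieldname, "reason": reason})
        else:
            seen_ids.add(rid)
            d = {"id": rid, "sex": sex.value}
            d.update(vals)
            accepted.append(d)

    data = pd.DataFrame(accepted, columns=list(COLUMNS))
    rej = pd.DataFrame(rejected, columns=["row", "field", "reason"])
    return Cohort(data, provenance=f"file:{path}", rejections=rej)


def write_cohort(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write the canonical columns to delimited text at full precision."""
    cohort.data.loc[:, list(COLUMNS)].to_csv(path, sep=sep, index=False)


def write_rejections(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    cohort.rejections.to_csv(path, sep=sep, index=False)
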