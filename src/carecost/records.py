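"""Survey microdata schema: one row per respondent, caregivers and non-caregivers.

The canonical in-memory container is a pandas DataFrame with the columns in
:data:`COLUMNS`; :func:`read_microdata` / :func:`write_microdata` round-trip it
through a plain CSV (comma-separated, UTF-8, header row mandatory).  Care and
employment-impact fields are present only where applicable: non-caregivers
carry empty strings / NaN in care columns, and a caregiver who skipped an item
carries the literal category ``"missing"``.

Row-level invariants (enforced on read):

* ``weight`` >= 0 and present for every row;
* care fields (hours 1-168, weeks 1-52, OOP bracket) present iff caregiver;
* productivity-impact flags only for ages 16-75: prolonged work cessation only
  for the currently non-employed, temporary cessation only for the currently
  employed, reduced hours / presenteeism items only for those who worked for
  pay in the past year.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import AGE_BAND_RETIRED, AGE_BANDS_WORKING, GENDERS, OOP_BRACKETS

#: Categorical codebooks (in-memory labels; "missing" = item skipped).
OOP_LABELS = OOP_BRACKETS + ("missing",)
DISTRACTION_LABELS = ("daily", "weekly", "monthly", "rarely_never", "missing")
CONCENTRATION_LABELS = ("none", "a_bit", "very_much", "missing")

#: Ages for which employment impact is assessed.
PRODUCTIVITY_AGE_MIN = 16
PRODUCTIVITY_AGE_MAX = 75

#: Fixed CSV column order.
COLUMNS = [
    "id",
    "weight",
    "is_caregiver",
    "gender",
    "age",
    "age_band",
    "care_hours_week",
    "care_weeks_year",
    "oop_bracket",
    "employed_now",
    "worked_past_year",
    "work_hours_week",
    "stopped_work_prolonged",
    "stopped_work_temporary",
    "reduced_hours",
    "distraction_freq",
    "concentration_loss",
]

_BOOL_COLS = [
    "is_caregiver",
    "employed_now",
    "worked_past_year",
    "stopped_work_prolonged",
    "stopped_work_temporary",
    "reduced_hours",
]


class MicrodataError(ValueError):
    """Raised when a microdata file fails schema validation."""


def age_band_of(age: int) -> str:
    """Decadal age band used for work-hours imputation (16_25 ... 66_75, 76_plus)."""
    if age < PRODUCTIVITY_AGE_MIN:
        raise ValueError(f"survey covers ages 16+, got {age}")
    if age > PRODUCTIVITY_AGE_MAX:
        return AGE_BAND_RETIRED
    idx = min((age - 16) // 10, len(AGE_BANDS_WORKING) - 1)
    return AGE_BANDS_WORKING[idx]


class CaregiverRecord(BaseModel):
    """A validated respondent row."""

    model_config = ConfigDict(extra="forbid")

    id: str
    weight: float = Field(ge=0)
    is_caregiver: bool
    gender: str
    age: int = Field(ge=PRODUCTIVITY_AGE_MIN, le=110)
    age_band: str
    care_hours_week: Optional[float] = None
    care_weeks_year: Optional[float] = None
    oop_bracket: Optional[str] = None
    employed_now: bool
    worked_past_year: bool
    work_hours_week: Optional[float] = None
    stopped_work_prolonged: bool = False
    stopped_work_temporary: bool = False
    reduced_hours: bool = False
    distraction_freq: Optional[str] = None
    concentration_loss: Optional[str] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "CaregiverRecord":
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.age_band != age_band_of(self.age):
            raise ValueError(
                f"age_band {self.age_band!r} inconsistent with age {self.age}"
            )
        if self.is_caregiver:
            if self.care_hours_week is None or not (1 <= self.care_hours_week <= 168):
                raise ValueError(
                    f"care_hours_week must be in [1, 168] for caregivers, "
                    f"got {self.care_hours_week}"
                )
            if self.care_weeks_year is None or not (1 <= self.care_weeks_year <= 52):
                raise ValueError(
                    f"care_weeks_year must be in [1, 52] for caregivers, "
                    f"got {self.care_weeks_year}"
                )
            if self.oop_bracket not in OOP_LABELS:
                raise ValueError(f"unknown OOP bracket {self.oop_bracket!r}")
        else:
            for f in ("care_hours_week", "care_weeks_year", "oop_bracket"):
                if getattr(self, f) is not None:
                    raise ValueError(f"{f} present on a non-caregiver row")
        if self.worked_past_year or self.employed_now:
            if self.work_hours_week is None or not (0 <= self.work_hours_week <= 168):
                raise ValueError(
                    "work_hours_week must be in [0, 168] for respondents who "
                    f"worked, got {self.work_hours_week}"
                )
        in_window = PRODUCTIVITY_AGE_MIN <= self.age <= PRODUCTIVITY_AGE_MAX
        if not in_window and (
            self.stopped_work_prolonged
            or self.stopped_work_temporary
            or self.reduced_hours
        ):
            raise ValueError("impact flags set outside the 16-75 age window")
        if self.stopped_work_prolonged and self.employed_now:
            raise ValueError("stopped_work_prolonged requires not employed_now")
        if self.stopped_work_temporary and not self.employed_now:
            raise ValueError("stopped_work_temporary requires employed_now")
        if self.reduced_hours and not self.worked_past_year:
            raise ValueError("reduced_hours requires worked_past_year")
        if self.distraction_freq is not None and (
            self.distraction_freq not in DISTRACTION_LABELS
        ):
            raise ValueError(f"unknown distraction label {self.distraction_freq!r}")
        if self.concentration_loss is not None and (
            self.concentration_loss not in CONCENTRATION_LABELS
        ):
            raise ValueError(
                f"unknown concentration label {self.concentration_loss!r}"
            )
        return self


def _parse_cell(col: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    if col in _BOOL_COLS:
        if raw in ("1", "True", "true"):
            return True
        if raw in ("0", "False", "false"):
            return False
        raise ValueError(f"{col}: expected 0/1, got {raw!r}")
    if col in ("weight", "care_hours_week", "care_weeks_year", "work_hours_week"):
        return float(raw)
    if col == "age":
        return int(float(raw))
    return raw


def records_to_frame(records: Iterable[CaregiverRecord]) -> pd.DataFrame:
    """Assemble validated records into the canonical DataFrame."""
    rows = [r.model_dump() for r in records]
    df = pd.DataFrame(rows, columns=COLUMNS)
    for col in _BOOL_COLS:
        df[col] = df[col].fillna(False).astype(bool)
    for col in ("weight", "care_hours_week", "care_weeks_year", "work_hours_week"):
        df[col] = df[col].astype(float)
    df["age"] = df["age"].astype(int)
    return df


def read_microdata(path: str | Path) -> pd.DataFrame:
    """Read and validate a respondent-level CSV.

    Every row is checked against :class:`CaregiverRecord`; offending rows are
    reported with their (0-based data) row index.  The returned frame preserves
    file order and row count.
    """
    path = Path(path)
    if not path.exists():
        raise MicrodataError(f"microdata file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise MicrodataError(f"missing columns: {missing_cols}")
    records: list[CaregiverRecord] = []
    problems: list[str] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        payload = {}
        try:
            for col in COLUMNS:
                payload[col] = _parse_cell(col, getattr(row, col))
            if payload["weight"] is None:
                raise ValueError("weight is mandatory")
            records.append(CaregiverRecord(**payload))
        except (ValueError, TypeError) as exc:
            msg = str(exc).splitlines()
            detail = next((ln.strip() for ln in msg if "Value error" in ln), msg[0])
            problems.append(f"row {i}: {detail}")
    if problems:
        shown = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        raise MicrodataError(f"{len(problems)} invalid rows: {shown}{more}")
    return records_to_frame(records)


def write_microdata(df: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical DataFrame as CSV, losslessly round-trippable.

    Booleans are encoded 1/0, not-applicable cells as empty strings.
    """
    out = df.loc[:, COLUMNS].copy()
    for col in _BOOL_COLS:
        out[col] = out[col].astype(int)

    def fmt(x) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return ""
        if isinstance(x, float) and x.is_integer():
            return str(int(x))
        return str(x)

    for col in ("care_hours_week", "care_weeks_year", "work_hours_week", "weight"):
        out[col] = out[col].map(fmt)
    for col in ("oop_bracket", "distraction_freq", "concentration_loss"):
        out[col] = out[col].map(lambda x: "" if x is None or x is np.nan else str(x))
    out.to_csv(path, index=False)


def validate_frame(df: pd.DataFrame) -> None:
    """Validate an in-memory frame (e.g. generator output) row by row."""
    problems = []
    for i, row in enumerate(df.itertuples(index=False)):
        payload = {col: getattr(row, col) for col in COLUMNS}
        for key, val in payload.items():
            if isinstance(val, float) and math.isnan(val):
                payload[key] = None
            elif isinstance(val, (np.bool_, np.integer, np.floating)):
                payload[key] = val.item()
        try:
            CaregiverRecord(**payload)
        except ValueError as exc:
            problems.append(f"row {i}: {exc}")
            if len(problems) >= 10:
                break
    if problems:
        raise MicrodataError("; ".join(problems))
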