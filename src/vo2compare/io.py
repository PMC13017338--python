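"""Cohort file reading and writing.

The cohort schema is a delimited text table with header
``id,age_years,sex,height_cm,weight_kg,mode,vo2peak_ml_min[,race,ethnicity]``
with sex coded M/F (or male/female) and mode treadmill/cycle. Reading
validates every row and accumulates line-numbered errors rather than
stopping at the first problem.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .subjects import Subject, SubjectValidationError

__all__ = ["CohortReadError", "read_cohort", "write_cohort"]

_REQUIRED = ("id", "age_years", "sex", "height_cm", "weight_kg", "mode", "vo2peak_ml_min")
_SEX_CODES = {"m": "male", "male": "male", "f": "female", "female": "female"}
_MODE_CODES = {"treadmill": "treadmill", "cycle": "cycle", "bike": "cycle"}


class CohortReadError(ValueError):
    """One or more cohort rows failed validation; message lists lines."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("cohort validation failed:\n" + "\n".join(errors))


def read_cohort(path: str | Path) -> list[Subject]:
    """Read and validate a cohort file into Subject records."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise CohortReadError(
            [f"{path.name}: header is missing columns: {', '.join(missing)}"]
        )
    errors: list[str] = []
    subjects: list[Subject] = []
    seen_ids: set[str] = set()
    for pos, row in enumerate(frame.to_dict(orient="records")):
        line = pos + 2  # header is line 1
        sid = str(row["id"])
        if sid in seen_ids:
            errors.append(f"line {line}: duplicate id {sid!r}")
            continue
        seen_ids.add(sid)
        sex = _SEX_CODES.get(str(row["sex"]).strip().lower())
        if sex is None:
            errors.append(f"line {line}: unknown sex code {row['sex']!r}")
            continue
        mode = _MODE_CODES.get(str(row["mode"]).strip().lower())
        if mode is None:
            errors.append(f"line {line}: unknown mode code {row['mode']!r}")
            continue
        try:
            numeric = {
                k: float(row[k])
                for k in ("age_years", "height_cm", "weight_kg", "vo2peak_ml_min")
            }
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric field in {sid!r}")
            continue
        race = row.get("race")
        ethnicity = row.get("ethnicity")
        try:
            subjects.append(
                Subject(
                    id=sid,
                    age=numeric["age_years"],
                    sex=sex,
                    height=numeric["height_cm"],
                    weight=numeric["weight_kg"],
                    mode=mode,
                    measured_vo2=numeric["vo2peak_ml_min"],
                    race=None if pd.isna(race) else str(race),
                    ethnicity=None if pd.isna(ethnicity) else str(ethnicity),
                )
            )
        except SubjectValidationError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise CohortReadError(errors)
    return subjects


def write_cohort(subjects: list[Subject], path: str | Path) -> None:
    """Write Subjects back to the cohort schema (inverse of read_cohort)."""
    rows = [
        {
            "id": s.id,
            "age_years": s.age,
            "sex": s.sex,
            "height_cm": s.height,
            "weight_kg": s.weight,
            "mode": s.mode,
            "vo2peak_ml_min": s.measured_vo2,
            "race": s.race,
            "ethnicity": s.ethnicity,
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
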