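"""Readers and writers for AE listings and patient disposition tables.

The canonical dialect is comma-separated text with a header row. Column
names are configurable through a column map so CDISC-AE-like exports
(USUBJID / AEDECOD / AETOXGR / AESTDY / AEENDY) load without editing the
file. Parsing is delegated to :mod:`pandas`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .model import AEEpisode, PatientRecord, ValidationError, arm_labels, patients_by_id

__all__ = [
    "AE_COLUMNS",
    "PATIENT_COLUMNS",
    "CDISC_AE_COLUMN_MAP",
    "ConfigurationError",
    "read_ae_table",
    "read_patient_table",
    "write_ae_table",
    "write_patient_table",
    "load_column_map",
    "load_weight_map",
]

#: canonical column names, field -> column
AE_COLUMNS = {
    "patient_id": "patient_id",
    "term": "term",
    "grade": "grade",
    "start_day": "start_day",
    "end_day": "end_day",
    "ongoing": "ongoing",
}
PATIENT_COLUMNS = {
    "patient_id": "patient_id",
    "arm": "arm",
    "last_study_day": "last_study_day",
}
#: field -> column map for CDISC SDTM AE domain style exports
CDISC_AE_COLUMN_MAP = {
    "patient_id": "USUBJID",
    "term": "AEDECOD",
    "grade": "AETOXGR",
    "start_day": "AESTDY",
    "end_day": "AEENDY",
}


class ConfigurationError(ValueError):
    """A required column is missing or a config file is malformed."""


def _resolve_columns(
    df: pd.DataFrame,
    defaults: Mapping[str, str],
    column_map: Mapping[str, str] | None,
    required: Sequence[str],
) -> dict[str, str]:
    mapping = dict(defaults)
    if column_map:
        unknown = set(column_map) - set(defaults)
        if unknown:
            raise ConfigurationError(
                f"column map names unknown fields: {sorted(unknown)}"
            )
        mapping.update(column_map)
    for fld in required:
        if mapping[fld] not in df.columns:
            raise ConfigurationError(
                f"required column {mapping[fld]!r} (field {fld!r}) not found; "
                f"available columns: {list(df.columns)}"
            )
    return mapping


def _is_blank(value: object) -> bool:
    return pd.isna(value) or (isinstance(value, str) and not value.strip())


def _as_int(value: object, what: str, row: int) -> int:
    try:
        number = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: non-integer {what}: {value!r}") from None
    if not number.is_integer():
        raise ValidationError(f"row {row}: non-integer {what}: {value!r}")
    return int(number)


_TRUTHY = {"1", "true", "yes", "y", "t"}


def read_ae_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[AEEpisode]:
    """Read an AE listing into validated :class:`AEEpisode` records.

    Rows with a blank grade or start day are rejected with the offending
    row index; an episode with a blank end day must carry a truthy ongoing
    flag (or the ongoing column may be absent only if every end day is
    populated).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = _resolve_columns(
        df, AE_COLUMNS, column_map, required=["patient_id", "term", "grade", "start_day"]
    )
    has_end = cols["end_day"] in df.columns
    has_ongoing = cols["ongoing"] in df.columns
    episodes: list[AEEpisode] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        record = dict(zip(df.columns, row))
        if _is_blank(record[cols["grade"]]):
            raise ValidationError(f"row {row_idx}: blank grade")
        if _is_blank(record[cols["start_day"]]):
            raise ValidationError(f"row {row_idx}: blank start day")
        grade = _as_int(record[cols["grade"]], "grade", row_idx)
        start = _as_int(record[cols["start_day"]], "start day", row_idx)
        end_raw = record[cols["end_day"]] if has_end else ""
        ongoing_raw = record[cols["ongoing"]] if has_ongoing else ""
        ongoing = str(ongoing_raw).strip().casefold() in _TRUTHY
        end: int | None
        if _is_blank(end_raw):
            end = None
            if not ongoing:
                raise ValidationError(
                    f"row {row_idx}: blank end day without ongoing flag"
                )
        else:
            end = _as_int(end_raw, "end day", row_idx)
            ongoing = False
        try:
            episodes.append(
                AEEpisode(
                    patient_id=str(record[cols["patient_id"]]).strip(),
                    term=record[cols["term"]],
                    grade=grade,
                    start_day=start,
                    end_day=end,
                    ongoing=ongoing,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {row_idx}: {exc}") from None
    return episodes


def read_patient_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[PatientRecord]:
    """Read a disposition table; patient ids must be unique and exactly two
    arm labels must be present."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = _resolve_columns(
        df, PATIENT_COLUMNS, column_map, required=["patient_id", "arm", "last_study_day"]
    )
    patients: list[PatientRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        record = dict(zip(df.columns, row))
        patients.append(
            PatientRecord(
                patient_id=str(record[cols["patient_id"]]).strip(),
                arm=str(record[cols["arm"]]).strip(),
                last_study_day=_as_int(
                    record[cols["last_study_day"]], "last study day", row_idx
                ),
            )
        )
    patients_by_id(patients)  # raises on duplicates
    arm_labels(patients)  # raises unless exactly two arms
    return patients


def write_ae_table(episodes: Iterable[AEEpisode], path: str | Path) -> None:
    """Write episodes in the canonical dialect (round-trips through
    :func:`read_ae_table`)."""
    rows = [
        {
            "patient_id": ep.patient_id,
            "term": ep.term,
            "grade": ep.grade,
            "start_day": ep.start_day,
            "end_day": "" if ep.end_day is None else ep.end_day,
            "ongoing": int(ep.ongoing),
        }
        for ep in episodes
    ]
    pd.DataFrame(rows, columns=list(AE_COLUMNS)).to_csv(path, index=False)


def write_patient_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "arm": p.arm,
            "last_study_day": p.last_study_day,
        }
        for p in patients
    ]
    pd.DataFrame(rows, columns=list(PATIENT_COLUMNS)).to_csv(path, index=False)


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a field -> column mapping from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"column map file {path} must hold a mapping")
    return {str(k): str(v) for k, v in data.items()}


def load_weight_map(path: str | Path) -> dict[str, float]:
    """Load a term -> positive weight mapping from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"weight map file {path} must hold a mapping")
    weights: dict[str, float] = {}
    for term, weight in data.items():
        w = float(weight)
        if w <= 0:
            raise ConfigurationError(f"weight for {term!r} must be > 0, got {w}")
        weights[str(term)] = w
    return weights
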