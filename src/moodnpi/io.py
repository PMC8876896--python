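"""CSV readers/writers for emotion records, NPI assessments and covariates.

All files are UTF-8, comma-delimited, with a mandatory header.  Readers
validate every row and raise a single error listing all offending lines
(1-based, counting the header as line 1).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .features import LABEL_CODES, encode_label

RECORD_COLUMNS = ["participant_id", "day", "rank", "label"]
ASSESSMENT_COLUMNS = ["participant_id", "day", "npi_total"]
PARTICIPANT_COLUMNS = ["participant_id", "sex", "age"]


class DataFormatError(ValueError):
    """A data file failed validation; the message lists every bad line."""


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")
    return df


def _to_int(value: str, what: str, line: int, errors: list[str], lo: int = 0) -> int:
    try:
        v = int(value)
    except ValueError:
        errors.append(f"line {line}: {what} {value!r} is not an integer")
        return lo
    if v < lo:
        errors.append(f"line {line}: {what} {v} is negative")
    return v


def read_records(path: str | Path) -> pd.DataFrame:
    """Read emotion records: ``participant_id,day,rank,label`` (+ ``code``)."""
    df = _read_csv(path, RECORD_COLUMNS)
    errors: list[str] = []
    days, ranks, codes = [], [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        days.append(_to_int(row.day, "day", line, errors))
        ranks.append(_to_int(row.rank, "rank", line, errors))
        try:
            codes.append(encode_label(row.label, row=line))
        except ValueError as exc:
            errors.append(str(exc))
            codes.append(0)
    if errors:
        raise DataFormatError(f"{path}:\n" + "\n".join(errors))
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "day": days,
            "rank": ranks,
            "label": df["label"].str.strip().str.lower(),
            "code": codes,
        }
    )
    dup = out.duplicated(subset=["participant_id", "day", "rank"])
    if dup.any():
        lines = [str(i + 2) for i in out.index[dup]]
        raise DataFormatError(
            f"{path}: duplicate (participant_id, day, rank) at line(s) {', '.join(lines)}"
        )
    return out


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_assessments(path: str | Path) -> pd.DataFrame:
    """Read NPI assessments: ``participant_id,day,npi_total`` (0-144)."""
    df = _read_csv(path, ASSESSMENT_COLUMNS)
    errors: list[str] = []
    days, totals = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        days.append(_to_int(row.day, "day", line, errors))
        total = _to_int(row.npi_total, "npi_total", line, errors)
        if total > 144:
            errors.append(
                f"line {line}: npi_total {total} exceeds the instrument maximum 144"
            )
        totals.append(total)
    out = pd.DataFrame(
        {"participant_id": df["participant_id"], "day": days, "npi_total": totals}
    )
    dup = out.duplicated(subset=["participant_id", "day"])
    if dup.any():
        lines = [str(i + 2) for i in out.index[dup]]
        errors.append(f"duplicate (participant_id, day) at line(s) {', '.join(lines)}")
    if errors:
        raise DataFormatError(f"{path}:\n" + "\n".join(errors))
    return out


def write_assessments(assessments: pd.DataFrame, path: str | Path) -> None:
    assessments[ASSESSMENT_COLUMNS].to_csv(path, index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read covariates: ``participant_id,sex,age`` (+ optional columns)."""
    df = _read_csv(path, PARTICIPANT_COLUMNS)
    errors: list[str] = []
    ages = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        if row.sex.strip().lower() not in ("male", "female"):
            errors.append(f"line {line}: sex {row.sex!r} not in {{male, female}}")
        try:
            ages.append(float(row.age))
        except ValueError:
            errors.append(f"line {line}: age {row.age!r} is not numeric")
            ages.append(float("nan"))
    if df["participant_id"].duplicated().any():
        errors.append("duplicate participant_id values")
    if errors:
        raise DataFormatError(f"{path}:\n" + "\n".join(errors))
    out = df.copy()
    out["sex"] = out["sex"].str.strip().str.lower()
    out["age"] = ages
    return out


def write_participants(participants: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in participants.columns if c != "latent_severity"]
    participants[cols].to_csv(path, index=False)


_ = LABEL_CODES  # re-exported for callers validating label vocabularies
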