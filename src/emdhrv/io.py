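"""Readers and writers for RR records, cohorts, feature tables, reports.

Formats
-------
* RR text: one RR interval in milliseconds per line; blank lines ignored.
* Beat CSV: header ``subject_id,condition,beat_time_s,rr_ms``, one row
  per beat; a whole cohort in one file.
* Manifest CSV: ``subject_id,condition,path`` pointing at RR text files.
* Feature table CSV: key columns then the 26 canonical feature names.
* Reports: JSON with sorted keys.

All numeric round-trips preserve at least 9 significant digits and all
writers are byte-deterministic for identical inputs.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParseError
from .features import FEATURE_NAMES
from .pipeline import KEY_COLUMNS
from .records import Cohort, RRSeries

__all__ = [
    "read_rr_text",
    "write_rr_text",
    "read_beat_csv",
    "write_beat_csv",
    "read_manifest",
    "write_manifest",
    "read_feature_table",
    "write_feature_table",
    "write_report",
]

_FLOAT_FMT = "%.12g"  # > 9 significant digits

BEAT_HEADER = ["subject_id", "condition", "beat_time_s", "rr_ms"]


def read_rr_text(path, subject_id: str = "unknown", condition: str = "unknown") -> RRSeries:
    """Read a one-RR-per-line text record (milliseconds)."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: not a numeric RR value: {stripped!r}"
                ) from None
    if len(values) < 2:
        raise DataError(f"{path}: need >= 2 RR intervals, got {len(values)}")
    return RRSeries(subject_id=subject_id, condition=condition,
                    rr_ms=np.asarray(values))


def write_rr_text(series: RRSeries, path) -> None:
    with open(path, "w") as fh:
        for value in series.rr_ms:
            fh.write(_FLOAT_FMT % value + "\n")


def read_beat_csv(path) -> Cohort:
    """Read a whole cohort from the beat CSV dialect."""
    frame = pd.read_csv(path)
    missing = [c for c in BEAT_HEADER if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dup = frame.duplicated(subset=["subject_id", "condition", "beat_time_s"])
    if dup.any():
        raise DataError(f"{path}: duplicate (subject, condition, beat_time) rows")
    cohort = Cohort(metadata={"source": str(path)})
    for (subject, condition), group in frame.groupby(
            ["subject_id", "condition"], sort=True):
        group = group.sort_values("beat_time_s")
        cohort.add(RRSeries(
            subject_id=str(subject),
            condition=str(condition),
            rr_ms=group["rr_ms"].to_numpy(float),
            beat_time_s=group["beat_time_s"].to_numpy(float),
            gapped=True,  # beat times are authoritative as stored
        ))
    return cohort


def write_beat_csv(cohort: Cohort, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(BEAT_HEADER)
        for key in sorted(cohort.records):
            series = cohort.records[key]
            for t, rr in zip(series.beat_time_s, series.rr_ms):
                writer.writerow([
                    series.subject_id, series.condition,
                    _FLOAT_FMT % t, _FLOAT_FMT % rr,
                ])


def read_manifest(path) -> Cohort:
    """Read a manifest CSV (subject_id, condition, path) of RR text files;
    relative paths resolve against the manifest's directory."""
    base = Path(path).parent
    frame = pd.read_csv(path)
    missing = [c for c in ("subject_id", "condition", "path")
               if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    cohort = Cohort(metadata={"source": str(path)})
    for row in frame.itertuples(index=False):
        record_path = Path(row.path)
        if not record_path.is_absolute():
            record_path = base / record_path
        cohort.add(read_rr_text(record_path, str(row.subject_id),
                                str(row.condition)))
    return cohort


def write_manifest(entries, path) -> None:
    """Write manifest rows of (subject_id, condition, path)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "condition", "path"])
        for subject_id, condition, record_path in entries:
            writer.writerow([subject_id, condition, record_path])


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table CSV; the 26 features keep canonical order."""
    missing = [c for c in KEY_COLUMNS + FEATURE_NAMES if c not in table.columns]
    if missing:
        raise FormatError(f"feature table is missing columns {missing}")
    extras = [c for c in table.columns if c not in KEY_COLUMNS + FEATURE_NAMES]
    ordered = table[KEY_COLUMNS + FEATURE_NAMES + extras]
    ordered.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in KEY_COLUMNS + FEATURE_NAMES if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return table


def write_report(report, path) -> None:
    """Serialize a report (dict or object with to_dict) as sorted-key JSON."""
    if hasattr(report, "to_dict"):
        report = report.to_dict()
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(obj)}")
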